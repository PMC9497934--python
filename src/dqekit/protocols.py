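"""Registry of standardized beam qualities and detector specifications.

Detector DQE measurements are made under heavily filtered reference beams
(RQA series).  Each beam quality is characterized by its half-value layer and
by the squared signal-to-noise ratio per unit air kerma, ``SNR_in^2 / Ka`` in
1/(mm^2 uGy).  Because an ideal photon-counting detector has ``SNR^2`` equal
to the photon count, this constant is numerically the photon fluence per air
kerma ratio, which converts a measured kerma into the input quanta ``Phi``
entering the DQE denominator.

Both the current (2015) and the superseded (2003) tabulations of the RQA
constants are registered; the 2015 values are the default.

Names are normalized before lookup — case, whitespace and punctuation are
ignored, so ``"rqa-5"``, ``"RQA 5"`` and ``"RQA5"`` are the same key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .exceptions import ConfigError, RegistryMissError

__all__ = [
    "BeamQuality",
    "DetectorSpec",
    "get_beam_quality",
    "get_detector_spec",
    "fluence_from_kerma",
    "load_registry",
    "beam_quality_names",
    "detector_names",
]


@dataclass(frozen=True)
class BeamQuality:
    """A standardized beam quality (RQA series).

    Attributes
    ----------
    name : str
        Canonical identifier, e.g. ``"RQA5"``.
    tube_voltage : float
        Tube voltage in kV.
    added_filtration : float
        Added aluminium filtration in mm Al.
    half_value_layer : float
        Half-value layer in mm Al.
    snr2_per_kerma : float
        Squared SNR per air kerma, 1/(mm^2 uGy); equals the photon fluence
        per air kerma ratio.
    protocol_version : str
        Tabulation the constants come from (``"2015"`` or ``"2003"``).
    """

    name: str
    tube_voltage: float
    added_filtration: float
    half_value_layer: float
    snr2_per_kerma: float
    protocol_version: str = "2015"

    def __post_init__(self) -> None:
        for field in ("tube_voltage", "added_filtration", "half_value_layer",
                      "snr2_per_kerma"):
            if not (getattr(self, field) > 0):
                raise ConfigError(f"BeamQuality.{field} must be > 0")


@dataclass(frozen=True)
class DetectorSpec:
    """One row of the detector specification sheet."""

    name: str
    scintillator_thickness_factor: float
    pixel_pitch: float  # micrometres
    matrix: tuple[int, int]
    detection_area: tuple[int, int]
    weight: float  # kg

    def __post_init__(self) -> None:
        if not (self.pixel_pitch > 0):
            raise ConfigError("pixel_pitch must be > 0")
        if not (self.scintillator_thickness_factor >= 1):
            raise ConfigError("scintillator_thickness_factor must be >= 1")
        if (self.matrix[0] < self.detection_area[0]
                or self.matrix[1] < self.detection_area[1]):
            raise ConfigError("matrix dimensions must cover the detection area")

    @property
    def pixel_pitch_mm(self) -> float:
        return self.pixel_pitch / 1000.0


def _normalize(name: str) -> str:
    """Casefold and strip all non-alphanumerics, so 'rqa-5' == 'RQA5'."""
    return re.sub(r"[^a-z0-9]+", "", name.casefold())


def _load_yaml(path: str | Path | None) -> Mapping:
    if path is None:
        text = (resources.files("dqekit") / "data" / "protocols.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


class _Registry:
    def __init__(self, raw: Mapping):
        self._beams: dict[str, tuple[str, Mapping]] = {}
        for name, rec in raw["beam_qualities"].items():
            self._beams[_normalize(name)] = (name, rec)
        self._detectors: dict[str, DetectorSpec] = {}
        for name, rec in raw["detectors"].items():
            spec = DetectorSpec(
                name=name,
                scintillator_thickness_factor=float(
                    rec["scintillator_thickness_factor"]),
                pixel_pitch=float(rec["pixel_pitch_um"]),
                matrix=tuple(int(v) for v in rec["matrix"]),
                detection_area=tuple(int(v) for v in rec["detection_area"]),
                weight=float(rec["weight_kg"]),
            )
            self._detectors[_normalize(name)] = spec

    def beam_names(self) -> list[str]:
        return [orig for orig, _ in self._beams.values()]

    def detector_names(self) -> list[str]:
        return [spec.name for spec in self._detectors.values()]

    def beam(self, name: str, protocol_version: str = "2015") -> BeamQuality:
        key = _normalize(name)
        if key not in self._beams:
            raise RegistryMissError(name, self.beam_names())
        canonical, rec = self._beams[key]
        version = str(protocol_version)
        vkey = f"iec_{version}"
        if vkey not in rec:
            raise RegistryMissError(
                f"{name} (protocol {version})",
                [k.removeprefix("iec_") for k in rec if k.startswith("iec_")],
            )
        vrec = rec[vkey]
        return BeamQuality(
            name=canonical,
            tube_voltage=float(rec["tube_voltage_kv"]),
            added_filtration=float(rec["added_filtration_mm_al"]),
            half_value_layer=float(vrec["half_value_layer_mm_al"]),
            snr2_per_kerma=float(vrec["snr2_per_kerma"]),
            protocol_version=version,
        )

    def detector(self, name: str) -> DetectorSpec:
        key = _normalize(name)
        if key not in self._detectors:
            raise RegistryMissError(name, self.detector_names())
        return self._detectors[key]


_DEFAULT: _Registry | None = None


def _default_registry() -> _Registry:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _Registry(_load_yaml(None))
    return _DEFAULT


def load_registry(path: str | Path) -> "_Registry":
    """Load a user registry file (same YAML schema as the packaged one)."""
    return _Registry(_load_yaml(path))


def beam_quality_names() -> list[str]:
    return _default_registry().beam_names()


def detector_names() -> list[str]:
    return _default_registry().detector_names()


def get_beam_quality(name: str, protocol_version: str = "2015",
                     registry: "_Registry | None" = None) -> BeamQuality:
    """Look up a registered beam quality.

    Raises :class:`RegistryMissError` (naming the valid keys) for unknown
    names; lookup is total over the registered RQA qualities.
    """
    reg = registry or _default_registry()
    return reg.beam(name, protocol_version)


def get_detector_spec(name: str,
                      registry: "_Registry | None" = None) -> DetectorSpec:
    """Look up a detector specification row by (normalized) name."""
    reg = registry or _default_registry()
    return reg.detector(name)


def fluence_from_kerma(bq: BeamQuality, kerma: float) -> float:
    """Photon fluence (photons/mm^2) at air kerma ``kerma`` (uGy).

    Uses the beam's photon fluence per air kerma ratio:
    ``Phi = Ka * snr2_per_kerma``.  Linear in kerma.
    """
    if kerma < 0:
        raise ConfigError(f"air kerma must be >= 0, got {kerma}")
    return float(kerma) * bq.snr2_per_kerma
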