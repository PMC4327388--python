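"""Acquisition parameters and pixel/nanometre unit conversion.

All modules share one convention: coordinates are 0-based with the origin at
the *centre* of the top-left pixel, ``x`` is the column index and ``y`` the
row index.  Physical distances are obtained by multiplying pixel distances by
``pixel_size_nm``.  The colocalisation threshold is stored in pixels (it may
be fractional) and converted to nanometres on demand, so that the two
quantities can never drift apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "AcquisitionConfig",
    "ConfigError",
    "PIXEL_SIZE_PRESETS",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid acquisition configuration."""


#: Named pixel-size presets (nm per pixel) for the two camera/objective
#: combinations the method was characterised with: a CoolSnap HQ behind a
#: ×60 objective (2 px threshold = 215 nm) and a CoolSnap ES behind a ×100
#: objective (3 px threshold = 193.5 nm).
PIXEL_SIZE_PRESETS: dict[str, float] = {
    "coolsnap_hq_60x": 107.5,
    "coolsnap_es_100x": 64.5,
}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Physical acquisition parameters shared by every analysis stage.

    Parameters
    ----------
    pixel_size_nm:
        Physical size of one camera pixel in the sample plane, in nm. Must
        be positive.  May be given as a preset name from
        :data:`PIXEL_SIZE_PRESETS`.
    threshold_px:
        Colocalisation distance threshold in pixels (fractional values are
        allowed).  Two particles closer than this (strictly) count as
        colocalised.
    channels:
        Ordered channel labels; order fixes the directed-pair ordering in
        reports.
    scramble_repeats, scramble_magnitude_px:
        Defaults for the scrambled-coordinate null model (see
        :mod:`spotcoloc.coloc`).
    """

    pixel_size_nm: float
    threshold_px: float
    channels: tuple[str, ...] = ("ch0", "ch1")
    scramble_repeats: int = 100
    scramble_magnitude_px: float = 20.0

    def __post_init__(self) -> None:
        if isinstance(self.pixel_size_nm, str):
            try:
                object.__setattr__(
                    self, "pixel_size_nm", PIXEL_SIZE_PRESETS[self.pixel_size_nm]
                )
            except KeyError:
                raise ConfigError(
                    f"unknown pixel size preset {self.pixel_size_nm!r}; "
                    f"known presets: {sorted(PIXEL_SIZE_PRESETS)}"
                ) from None
        if not (self.pixel_size_nm > 0):
            raise ConfigError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if not (self.threshold_px > 0):
            raise ConfigError(f"threshold_px must be > 0, got {self.threshold_px}")
        if len(self.channels) < 1:
            raise ConfigError("at least one channel label is required")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError(f"duplicate channel labels: {self.channels}")
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.scramble_repeats < 1:
            raise ConfigError("scramble_repeats must be >= 1")
        if not (self.scramble_magnitude_px > 0):
            raise ConfigError("scramble_magnitude_px must be > 0")

    @property
    def threshold_nm(self) -> float:
        """Colocalisation threshold in nanometres (= threshold_px x pixel size)."""
        return self.threshold_px * self.pixel_size_nm

    @classmethod
    def from_threshold_nm(
        cls,
        pixel_size_nm: float,
        threshold_nm: float,
        channels: Sequence[str] = ("ch0", "ch1"),
        **kwargs,
    ) -> "AcquisitionConfig":
        """Build a config from a threshold expressed in nanometres."""
        if not (pixel_size_nm > 0):
            raise ConfigError(f"pixel_size_nm must be > 0, got {pixel_size_nm}")
        return cls(
            pixel_size_nm=pixel_size_nm,
            threshold_px=threshold_nm / pixel_size_nm,
            channels=tuple(channels),
            **kwargs,
        )

    def nm_to_px(self, nm: float) -> float:
        return nm / self.pixel_size_nm

    def px_to_nm(self, px: float) -> float:
        return px * self.pixel_size_nm

    def with_channels(self, channels: Sequence[str]) -> "AcquisitionConfig":
        return replace(self, channels=tuple(channels))


def load_config(path: str | Path) -> AcquisitionConfig:
    """Read an :class:`AcquisitionConfig` from a YAML or JSON file.

    Recognised keys: ``pixel_size_nm`` (number or preset name), exactly one
    of ``threshold_px`` / ``threshold_nm``, optional ``channels``,
    ``scramble_repeats`` and ``scramble_magnitude_px``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> AcquisitionConfig:
    """Build a config from a plain mapping (parsed YAML/JSON)."""
    known = {
        "pixel_size_nm",
        "threshold_px",
        "threshold_nm",
        "channels",
        "scramble_repeats",
        "scramble_magnitude_px",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "pixel_size_nm" not in raw:
        raise ConfigError("missing required key: pixel_size_nm")
    has_px = "threshold_px" in raw
    has_nm = "threshold_nm" in raw
    if has_px == has_nm:
        raise ConfigError(
            "exactly one of threshold_px / threshold_nm must be given"
        )
    extras = {
        k: raw[k]
        for k in ("scramble_repeats", "scramble_magnitude_px")
        if k in raw
    }
    channels = tuple(raw.get("channels", ("ch0", "ch1")))
    if has_px:
        return AcquisitionConfig(
            pixel_size_nm=raw["pixel_size_nm"],
            threshold_px=raw["threshold_px"],
            channels=channels,
            **extras,
        )
    pixel_size = raw["pixel_size_nm"]
    if isinstance(pixel_size, str):
        try:
            pixel_size = PIXEL_SIZE_PRESETS[pixel_size]
        except KeyError:
            raise ConfigError(f"unknown pixel size preset {pixel_size!r}") from None
    return AcquisitionConfig.from_threshold_nm(
        pixel_size_nm=pixel_size,
        threshold_nm=raw["threshold_nm"],
        channels=channels,
        **extras,
    )
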