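"""Axial intensity profiles: extraction, length standardization, z-scoring.

Given an oriented cell (vertical axis, apex at row ``tip_row``), the axial
profile is the mean intensity of mask pixels in each row, index 0 = tip.
Profiles are then standardized to a fixed length (default 110 px, linear
interpolation with exact endpoints) and z-scored to mean 0, population
standard deviation 1, which removes per-probe gain and offset and makes
profiles comparable across probes and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DisconnectedMaskError, FlatProfileError
from .geometry import OrientedCell

__all__ = [
    "STANDARD_LENGTH",
    "AxisProfile",
    "NormalizedProfile",
    "axial_profile",
    "resample_profile",
    "zscore",
    "normalize_profile",
]

STANDARD_LENGTH = 110  # default standard cell length in pixels


@dataclass
class AxisProfile:
    """Raw mean-intensity profile along the apical–basal axis (index 0 = tip)."""

    values: np.ndarray
    length_px: int
    probe: str = ""
    replicate_id: str = ""
    timepoint: int = -1


@dataclass
class NormalizedProfile:
    """Length-standardized, z-scored axial profile (index 0 = tip)."""

    values: np.ndarray
    L: int = STANDARD_LENGTH
    probe: str = ""
    replicate_id: str = ""
    timepoint: int = -1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.L:
            raise ValueError(f"expected {self.L} values, got {self.values.size}")


def axial_profile(cell: OrientedCell, **meta) -> AxisProfile:
    """Mean intensity over mask pixels per row, from tip to base.

    Background pixels never enter the mean.  An interior row with no mask
    pixels indicates a disconnected mask and is an error.
    """
    counts = cell.mask[cell.tip_row : cell.base_row + 1].sum(axis=1)
    if np.any(counts == 0):
        bad = np.nonzero(counts == 0)[0] + cell.tip_row
        raise DisconnectedMaskError(
            f"mask has no pixels in interior row(s) {bad.tolist()}"
        )
    sums = np.where(
        cell.mask[cell.tip_row : cell.base_row + 1],
        cell.image[cell.tip_row : cell.base_row + 1],
        0.0,
    ).sum(axis=1)
    values = sums / counts
    return AxisProfile(values=values, length_px=int(values.size), **meta)


def resample_profile(profile, L: int = STANDARD_LENGTH) -> np.ndarray:
    """Linearly interpolate a profile to exactly ``L`` samples.

    Sample ``i`` is taken at position ``i*(n-1)/(L-1)`` on the input grid;
    endpoints are preserved exactly.
    """
    values = profile.values if isinstance(profile, AxisProfile) else profile
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("profile must have at least 2 samples to resample")
    if L < 2:
        raise ValueError("target length must be >= 2")
    pos = np.arange(L) * (n - 1) / (L - 1)
    out = np.interp(pos, np.arange(n), values)
    out[0] = values[0]
    out[-1] = values[-1]
    return out


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, population standard deviation 1 (divisor n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = values.std()  # population sd, divisor n
    scale = max(float(np.abs(values).max()), 1.0)
    if not np.isfinite(sd) or sd <= 1e-12 * scale:
        raise FlatProfileError(
            "flat profile (zero variance): empty or saturated cell?"
        )
    return (values - values.mean()) / sd


def normalize_profile(profile: AxisProfile, L: int = STANDARD_LENGTH) -> NormalizedProfile:
    """Full standardization: resample to ``L`` then z-score."""
    return NormalizedProfile(
        values=zscore(resample_profile(profile, L)),
        L=L,
        probe=profile.probe,
        replicate_id=profile.replicate_id,
        timepoint=profile.timepoint,
    )
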