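"""Division-plane position along the apical–basal axis.

The asymmetric division plane is annotated manually (a point on the axis
of the division frame).  After orienting the cell, its position is
expressed as a percentage of cell length from the tip and compared with
half of the compartment boundary — the midpoint of the apical compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DivisionPlaneMeasurement",
    "division_plane_position",
    "boundary_vs_plane",
]


@dataclass(frozen=True)
class DivisionPlaneMeasurement:
    plane_row: float
    tip_row: float
    base_row: float
    pct_from_tip: float


def division_plane_position(plane_row: float, tip_row: float, base_row: float) -> float:
    """Relative plane position, 100·(plane−tip)/(base−tip).

    Report with one decimal, e.g. ``round(x, 1)``.
    """
    if base_row <= tip_row:
        raise ValueError("base_row must exceed tip_row")
    if not (tip_row <= plane_row <= base_row):
        raise ValueError(
            f"division plane at row {plane_row} lies outside the cell "
            f"extent [{tip_row}, {base_row}]"
        )
    return float(100.0 * (plane_row - tip_row) / (base_row - tip_row))


def boundary_vs_plane(boundary_pct: float, plane_pcts) -> dict:
    """Summarize plane positions against half the apical compartment.

    Returns mean, sample SD (divisor n−1; ``None`` for n = 1), n,
    ``half_boundary = boundary_pct/2`` and ``delta = mean − half_boundary``.
    """
    planes = np.asarray(list(plane_pcts), dtype=float)
    if planes.size == 0:
        raise ValueError("no plane positions supplied")
    mean = float(planes.mean())
    sd = float(planes.std(ddof=1)) if planes.size > 1 else None
    half = boundary_pct / 2.0
    return {
        "mean": mean,
        "sd": sd,
        "n": int(planes.size),
        "half_boundary": half,
        "delta": mean - half,
    }
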