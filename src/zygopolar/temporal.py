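"""Event-anchored time normalization.

The elongation phase of a zygote movie runs from the manually annotated
onset of cell elongation to the frame just before the asymmetric cell
division.  Because the absolute duration varies strongly between movies,
the phase is resampled to ``k`` normalized time points (T = 0 .. k-1) at
equal intervals, T = 0 pinned to the onset frame and T = k-1 to the
pre-division frame.  The nearest raw frame is selected for each point
(round-half-up); no temporal interpolation is performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = ["TimeNormalization", "select_normalized_frames"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_normalized_frames(onset: int, predivision: int, k: int = 10) -> list[int]:
    """Select ``k`` raw-frame indices at equal intervals in [onset, predivision].

    Index ``i`` (0-based) maps to ``round(onset + i*(predivision-onset)/(k-1))``
    with round-half-up; both endpoints are hit exactly.

    Raises
    ------
    ValueError
        If the elongation window is empty (``predivision <= onset``) or
        ``k < 2``.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if predivision <= onset:
        raise ValueError(
            f"empty elongation window: predivision ({predivision}) must exceed "
            f"onset ({onset})"
        )
    span = predivision - onset
    frames = [_round_half_up(onset + i * span / (k - 1)) for i in range(k)]
    frames[0] = onset
    frames[-1] = predivision
    if span < k - 1:
        warnings.warn(
            f"elongation window of {span + 1} frames is shorter than k={k}; "
            "some frames are selected more than once",
            stacklevel=2,
        )
    return frames


@dataclass
class TimeNormalization:
    """Mapping from normalized time points T=0..k-1 to raw frame indices."""

    onset_frame: int
    predivision_frame: int
    k: int = 10
    selected_frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.selected_frames:
            self.selected_frames = select_normalized_frames(
                self.onset_frame, self.predivision_frame, self.k
            )
        if len(self.selected_frames) != self.k:
            raise ValueError("selected_frames length does not equal k")
        if self.selected_frames[0] != self.onset_frame:
            raise ValueError("selected_frames[0] must equal onset_frame")
        if self.selected_frames[-1] != self.predivision_frame:
            raise ValueError("selected_frames[-1] must equal predivision_frame")
        if any(b < a for a, b in zip(self.selected_frames, self.selected_frames[1:])):
            raise ValueError("selected_frames must be non-decreasing")
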