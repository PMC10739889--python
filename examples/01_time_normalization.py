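"""Event-anchored time normalization.

A zygote movie is annotated with the frame where cell elongation starts
and the last frame before the asymmetric division.  Ten normalized time
points (T = 0..9) are placed at equal intervals between the two events,
whatever the movie's absolute duration.
"""

from zygopolar import select_normalized_frames

for onset, prediv in [(0, 9), (0, 18), (2, 12), (5, 47)]:
    frames = select_normalized_frames(onset, prediv, k=10)
    print(f"onset={onset:2d} predivision={prediv:2d} -> frames {frames}")

print(
    "\nEach list maps T=0..9 onto raw frame indices; endpoints are the two"
    "\nannotated events, interior points the nearest raw frames."
)
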