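"""Independent brute-force oracle for reflected path lengths.

Instead of the closed-form image set, paths are built by recursively
mirroring the source across the surface (z -> -z) and the seafloor
(z -> 2D - z).  Consecutive reflections in a two-plane waveguide must
alternate, so the enumeration is two chains (surface-first and
bottom-first) of increasing bounce count.  Used only as a reference in
tests; deliberately shares no code with the package's enumerator.
"""

from __future__ import annotations

import math


def unfold_paths(
    water_depth: float,
    tag_depth: float,
    receiver_depth: float,
    horizontal_range: float,
    max_path_length: float,
) -> list[tuple[float, int, int]]:
    """All reflected paths with length <= max_path_length, as a sorted list
    of (path_length, surface_bounces, bottom_bounces)."""
    D = water_depth
    # every two extra bounces push the image at least 2D further out
    max_bounces = int(max_path_length / (2 * D)) * 2 + 6
    found: list[tuple[float, int, int]] = []

    def chain(z: float, s: int, b: int, last: str) -> None:
        if s + b > max_bounces:
            return
        if s + b >= 1:
            L = math.hypot(horizontal_range, z - receiver_depth)
            if L <= max_path_length:
                found.append((L, s, b))
        if last != "surface":
            chain(-z, s + 1, b, "surface")
        if last != "bottom":
            chain(2 * D - z, s, b + 1, "bottom")

    chain(-tag_depth, 1, 0, "surface")
    chain(2 * D - tag_depth, 0, 1, "bottom")
    found.sort()
    return found
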