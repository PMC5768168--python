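"""Close-proximity detection interference (CPDI) prediction.

CPDI is the failure of an acoustic receiver to log transmissions from a
nearby tag: a reflected copy of a ping that arrives *after* the receiver's
post-ping blanking interval, while still loud enough to be detected, is
mistaken for the next ping of the coded train and the whole transmission is
rejected.

Every reflected path is placed in one of three categories against the
receiver's contract (blanking interval ``BI``, average maximum detection
radius ``AMDR``):

1. relative delay <= BI and path length <= AMDR: absorbed by blanking,
   harmless;
2. relative delay >  BI and path length <= AMDR: detectable and late —
   produces CPDI;
3. path length > AMDR: too attenuated to be detected, harmless.

A grid point (tag position) is predicted to experience CPDI when at least
one of its multipaths is category 2.  Both boundary comparisons are
inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    Category,
    Environment,
    MultipathArrival,
    PairGeometry,
    ReceiverSpec,
    direct_path_length,
    enumerate_multipaths,
)

__all__ = [
    "CPDIGrid",
    "classify_multipath",
    "predict_cpdi_point",
    "predict_cpdi_map",
    "cpdi_extent",
    "critical_depth",
    "critical_path_difference",
    "surface_reflection_extent",
]


@dataclass(frozen=True)
class CPDIGrid:
    """Range x tag-depth lattice of CPDI predictions for one receiver.

    ``cpdi_flag[i, j]`` refers to tag depth ``depth_axis[i]`` at range
    ``range_axis[j]``; ``n_category2`` counts the offending multipaths per
    cell.  ``provenance`` echoes the configuration that produced the grid.
    """

    range_axis: np.ndarray
    depth_axis: np.ndarray
    cpdi_flag: np.ndarray
    n_category2: np.ndarray
    receiver_depth: float
    environment: Environment
    receiver: ReceiverSpec
    max_arrivals: int | None = None
    surface_only: bool = False

    def __post_init__(self) -> None:
        expected = (len(self.depth_axis), len(self.range_axis))
        if self.cpdi_flag.shape != expected or self.n_category2.shape != expected:
            raise ValueError(
                f"matrix shape {self.cpdi_flag.shape} does not match axes {expected}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: range_m, tag_depth_m, cpdi (0/1), n_cat2."""
        rr, dd = np.meshgrid(self.range_axis, self.depth_axis)
        return pd.DataFrame(
            {
                "range_m": rr.ravel(),
                "tag_depth_m": dd.ravel(),
                "cpdi": self.cpdi_flag.ravel().astype(int),
                "n_cat2": self.n_category2.ravel().astype(int),
            }
        )

    def extent_report(self) -> dict:
        """Per-depth CPDI extents plus a configuration echo (JSON-ready)."""
        return {
            "receiver_depth_m": self.receiver_depth,
            "water_depth_m": self.environment.water_depth,
            "sound_speed_m_s": self.environment.sound_speed,
            "blanking_interval_s": self.receiver.blanking_interval,
            "amdr_m": self.receiver.amdr,
            "max_arrivals": self.max_arrivals,
            "surface_only": self.surface_only,
            "resolution_m": float(self.range_axis[1] - self.range_axis[0])
            if len(self.range_axis) > 1
            else None,
            "extent_by_tag_depth_m": {
                f"{d:g}": cpdi_extent(self, d) for d in self.depth_axis
            },
        }


def classify_multipath(
    arrival: MultipathArrival, spec: ReceiverSpec, env: Environment
) -> MultipathArrival:
    """Return a copy of ``arrival`` with its CPDI category assigned."""
    if arrival.path_length > spec.amdr:
        cat = Category.BEYOND_AMDR
    elif arrival.relative_delay <= spec.blanking_interval:
        cat = Category.WITHIN_BLANKING
    else:
        cat = Category.CPDI_PRODUCING
    return arrival.with_category(cat)


def _select_arrivals(
    env: Environment,
    spec: ReceiverSpec,
    geom: PairGeometry,
    max_arrivals: int | None,
    surface_only: bool,
) -> list[MultipathArrival]:
    arrivals = enumerate_multipaths(env, geom, max_path_length=spec.amdr,
                                    max_arrivals=max_arrivals)
    if surface_only:
        arrivals = [a for a in arrivals if a.signature == (1, 0)]
    return arrivals


def predict_cpdi_point(
    env: Environment,
    spec: ReceiverSpec,
    receiver_depth: float,
    tag_depth: float,
    horizontal_range: float,
    max_arrivals: int | None = None,
    surface_only: bool = False,
) -> tuple[bool, int]:
    """CPDI prediction for a single tag position.

    Returns ``(flag, n_category2)``: the flag is true iff at least one
    multipath with length <= AMDR arrives later than the blanking interval.
    ``max_arrivals`` restricts consideration to the earliest arrivals;
    ``surface_only`` restricts it to the first surface reflection.
    """
    geom = PairGeometry(tag_depth, receiver_depth, horizontal_range)
    arrivals = _select_arrivals(env, spec, geom, max_arrivals, surface_only)
    n_cat2 = sum(
        1
        for a in arrivals
        if classify_multipath(a, spec, env).category == Category.CPDI_PRODUCING
    )
    return n_cat2 > 0, n_cat2


def predict_cpdi_map(
    env: Environment,
    spec: ReceiverSpec,
    receiver_depth: float,
    max_range: float,
    depth_axis: Sequence[float],
    resolution: float = 1.0,
    max_arrivals: int | None = None,
    surface_only: bool = False,
) -> CPDIGrid:
    """Evaluate the CPDI criterion on a range x depth lattice.

    Grid ranges run 0, resolution, 2*resolution, ... up to and including
    ``max_range``; each node is a candidate tag position with the receiver
    fixed at range 0.  Output is deterministic for identical inputs.
    """
    if not resolution > 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")
    if max_range < resolution:
        raise ValueError(f"max_range={max_range} smaller than resolution={resolution}")
    depth_axis = np.asarray(sorted(depth_axis), dtype=float)
    if depth_axis.size == 0:
        raise ValueError("depth_axis is empty")
    n_steps = int(math.floor(max_range / resolution + 1e-9))
    range_axis = np.arange(n_steps + 1, dtype=float) * resolution

    flags = np.zeros((depth_axis.size, range_axis.size), dtype=bool)
    counts = np.zeros_like(flags, dtype=int)
    for i, zt in enumerate(depth_axis):
        for j, r in enumerate(range_axis):
            flag, n2 = predict_cpdi_point(
                env, spec, receiver_depth, zt, r,
                max_arrivals=max_arrivals, surface_only=surface_only,
            )
            flags[i, j] = flag
            counts[i, j] = n2
    return CPDIGrid(
        range_axis=range_axis,
        depth_axis=depth_axis,
        cpdi_flag=flags,
        n_category2=counts,
        receiver_depth=receiver_depth,
        environment=env,
        receiver=spec,
        max_arrivals=max_arrivals,
        surface_only=surface_only,
    )


def cpdi_extent(grid: CPDIGrid, tag_depth: float) -> float:
    """Maximum flagged range (m) for one tag depth; 0 if nothing is flagged."""
    matches = np.isclose(grid.depth_axis, tag_depth)
    if not matches.any():
        raise ValueError(
            f"tag_depth={tag_depth} not on grid depth axis {grid.depth_axis}"
        )
    row = grid.cpdi_flag[int(np.argmax(matches))]
    if not row.any():
        return 0.0
    return float(grid.range_axis[np.nonzero(row)[0][-1]])


def critical_path_difference(sound_speed: float, blanking_interval: float) -> float:
    """Path-length excess c*BI (m) a multipath needs to outlast the blanking."""
    return sound_speed * blanking_interval


def critical_depth(sound_speed: float, blanking_interval: float) -> float:
    """Depth at which the first surface reflection starts to produce CPDI.

    For a colocated, equal-depth tag/receiver pair at depth ``d`` the surface
    bounce travels ``2d`` further than the direct path, so its delay exceeds
    the blanking interval once ``d > c*BI/2``.
    """
    if sound_speed < 0 or blanking_interval < 0:
        raise ValueError("sound_speed and blanking_interval must be non-negative")
    return sound_speed * blanking_interval / 2.0


def surface_reflection_extent(
    tag_depth: float,
    receiver_depth: float,
    sound_speed: float = 1530.0,
    blanking_interval: float = 0.260,
    amdr: float = math.inf,
) -> float:
    """Closed-form CPDI extent (m) considering only the first surface bounce,
    for a tag and receiver at equal depth.

    With image distance ``v = zt + zr`` and ``X = c*BI``, the reflection is
    late while ``sqrt(r**2 + v**2) - r > X``, i.e. out to
    ``r = (v**2 - X**2) / (2X)``; the path must additionally stay within the
    AMDR.  Continuous (not grid-quantised) value.
    """
    if not math.isclose(tag_depth, receiver_depth):
        raise ValueError("closed form requires tag_depth == receiver_depth")
    v = tag_depth + receiver_depth
    X = critical_path_difference(sound_speed, blanking_interval)
    if v <= X or v > amdr:
        return 0.0
    r_delay = (v**2 - X**2) / (2 * X)
    r_amdr = math.sqrt(amdr**2 - v**2) if amdr < math.inf else math.inf
    return max(0.0, min(r_delay, r_amdr))
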