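"""Image-source ray geometry for a flat-surface / flat-bottom waveguide.

A tag and a receiver sit in a water column of uniform depth ``D`` with a
constant sound speed ``c`` (straight-line propagation; no refraction).  Every
reflected propagation path between them corresponds to a mirror image of the
tag obtained by repeatedly reflecting its depth across the sea surface
(``z = 0``) and the seafloor (``z = D``).  The full image set lives at signed
depths ``z = 2 m D + zt`` and ``z = 2 m D - zt`` over the integers ``m``; the
path length for an image at ``z`` is ``sqrt(r**2 + (z - zr)**2)`` where ``r``
is the horizontal range and ``zr`` the receiver depth.  The ``(m=0, +)``
image is the tag itself and gives the direct path.

Relative arrival delays are ``(L - L_direct) / c`` and the per-path amplitude
scalar follows a spherical-spreading ``1/L`` law; no surface or seafloor
reflection loss is applied, so predictions err on the side of reporting a
multipath as detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Environment",
    "PairGeometry",
    "MultipathArrival",
    "ReceiverSpec",
    "Category",
    "heights_to_depths",
    "direct_path_length",
    "enumerate_multipaths",
    "relative_delay_curve",
]


class Category(IntEnum):
    """Multipath classification with respect to a receiver's detection contract.

    1: arrives within the blanking interval and is detectable -> harmless.
    2: arrives after the blanking interval and is detectable -> causes CPDI.
    3: path longer than the AMDR -> too attenuated to be detected.
    """

    UNSET = 0
    WITHIN_BLANKING = 1
    CPDI_PRODUCING = 2
    BEYOND_AMDR = 3


@dataclass(frozen=True)
class Environment:
    """Flat waveguide: water depth ``D`` (m) and sound speed ``c`` (m/s)."""

    water_depth: float
    sound_speed: float = 1530.0

    def __post_init__(self) -> None:
        if not self.water_depth > 0:
            raise ValueError(f"water_depth must be > 0, got {self.water_depth}")
        if not self.sound_speed > 0:
            raise ValueError(f"sound_speed must be > 0, got {self.sound_speed}")


@dataclass(frozen=True)
class PairGeometry:
    """Tag/receiver positions: depths below the surface (m) and horizontal range (m)."""

    tag_depth: float
    receiver_depth: float
    horizontal_range: float

    def validate(self, env: Environment) -> None:
        for name, z in (("tag_depth", self.tag_depth), ("receiver_depth", self.receiver_depth)):
            if not 0 <= z <= env.water_depth:
                raise ValueError(
                    f"{name}={z} m outside the water column [0, {env.water_depth}] m"
                )
        if self.horizontal_range < 0:
            raise ValueError(f"horizontal_range must be >= 0, got {self.horizontal_range}")


@dataclass(frozen=True)
class MultipathArrival:
    """One reflected path: length, bounce counts, delay and amplitude scalar.

    ``amplitude_scalar`` is the received-level factor ``1/path_length``
    (equivalently ``10**(-log10(L))``); ``relative_delay`` is measured from
    the direct arrival.
    """

    path_length: float
    vertical_image_distance: float
    surface_bounces: int
    bottom_bounces: int
    relative_delay: float
    amplitude_scalar: float
    category: Category = Category.UNSET

    @property
    def signature(self) -> tuple[int, int]:
        return (self.surface_bounces, self.bottom_bounces)

    def with_category(self, category: Category) -> "MultipathArrival":
        return replace(self, category=category)


@dataclass(frozen=True)
class ReceiverSpec:
    """The receiver's detection contract.

    blanking_interval: dead time (s) after each registered ping during which
        further arrivals are ignored (0.260 s is the longest the modelled
        receiver offers and the default).
    amdr: average maximum detection radius (m) — the longest path the
        receiver can hear, estimated from range testing.
    pings_per_train: pings making up one coded transmission.
    """

    amdr: float
    blanking_interval: float = 0.260
    pings_per_train: int = 8

    def __post_init__(self) -> None:
        if not self.blanking_interval > 0:
            raise ValueError(f"blanking_interval must be > 0, got {self.blanking_interval}")
        if not self.amdr > 0:
            raise ValueError(f"amdr must be > 0, got {self.amdr}")
        if self.pings_per_train < 7:
            raise ValueError(f"pings_per_train must be >= 7, got {self.pings_per_train}")


def heights_to_depths(
    env: Environment, tag_height: float, receiver_height: float
) -> tuple[float, float]:
    """Convert heights above the seafloor to depths below the surface."""
    for name, h in (("tag_height", tag_height), ("receiver_height", receiver_height)):
        if not 0 <= h <= env.water_depth:
            raise ValueError(
                f"{name}={h} m outside [0, {env.water_depth}] m water column"
            )
    return env.water_depth - tag_height, env.water_depth - receiver_height


def direct_path_length(geom: PairGeometry) -> float:
    """Length of the unreflected tag-to-receiver path (m)."""
    return math.hypot(geom.horizontal_range, geom.tag_depth - geom.receiver_depth)


def _bounce_counts(m: int, sign: int) -> tuple[int, int]:
    """(surface, bottom) bounce counts for image z = 2*m*D + sign*zt."""
    if sign == +1:
        return (abs(m), abs(m))
    if m == 0:
        return (1, 0)
    if m > 0:
        return (m - 1, m)
    return (abs(m) + 1, abs(m))


def _image_candidates(env: Environment, tag_depth: float, max_v: float):
    """Yield (v_offset_base, sign, m) image terms; enumeration is complete for
    every image whose vertical offset magnitude can be <= max_v."""
    D = env.water_depth
    # |2mD +/- zt - zr| >= 2|m|D - zt - zr >= 2|m|D - 2D, so orders beyond
    # this bound cannot reach max_v for any receiver depth in the column.
    max_order = int(math.ceil((max_v + 2 * D) / (2 * D))) + 1
    for m in range(-max_order, max_order + 1):
        for sign in (+1, -1):
            yield m, sign, 2 * m * D + sign * tag_depth


def enumerate_multipaths(
    env: Environment,
    geom: PairGeometry,
    max_path_length: float,
    max_arrivals: int | None = None,
) -> list[MultipathArrival]:
    """Enumerate every reflected path with length <= ``max_path_length``.

    The direct path is excluded from the returned list (its length is
    available via :func:`direct_path_length`).  Paths are sorted by length,
    ties broken by ascending (surface_bounces, bottom_bounces).  When
    ``max_arrivals`` is given only that many shortest paths are returned,
    mimicking receivers/simulations that consider a fixed number of earliest
    arrivals.
    """
    geom.validate(env)
    if not max_path_length > 0:
        raise ValueError(f"max_path_length must be > 0, got {max_path_length}")
    if max_arrivals is not None and max_arrivals < 0:
        raise ValueError(f"max_arrivals must be >= 0, got {max_arrivals}")

    r = geom.horizontal_range
    zr = geom.receiver_depth
    L_direct = direct_path_length(geom)
    c = env.sound_speed

    out: list[MultipathArrival] = []
    for m, sign, z in _image_candidates(env, geom.tag_depth, max_path_length):
        if m == 0 and sign == +1:
            continue  # direct path
        v = abs(z - zr)
        L = math.hypot(r, v)
        if L <= max_path_length:
            s, b = _bounce_counts(m, sign)
            out.append(
                MultipathArrival(
                    path_length=L,
                    vertical_image_distance=v,
                    surface_bounces=s,
                    bottom_bounces=b,
                    relative_delay=(L - L_direct) / c,
                    amplitude_scalar=1.0 / L if L > 0 else math.inf,
                )
            )
    out.sort(key=lambda a: (a.path_length, a.surface_bounces, a.bottom_bounces))
    if max_arrivals is not None:
        out = out[:max_arrivals]
    return out


def relative_delay_curve(
    env: Environment,
    tag_depth: float,
    receiver_depth: float,
    ranges: Sequence[float] | np.ndarray,
    arrival_selector: tuple[int, int] = (1, 0),
) -> np.ndarray:
    """Relative delay (s) of one reflected arrival as a function of range.

    ``arrival_selector`` is the (surface_bounces, bottom_bounces) signature;
    the default ``(1, 0)`` is the first surface reflection.  Where several
    images share a signature the shortest is used.  For fixed depths the
    delay decreases strictly with range (direct and reflected paths converge).
    """
    ranges = np.asarray(ranges, dtype=float)
    if np.any(ranges < 0):
        raise ValueError("ranges must be non-negative")
    s_want, b_want = arrival_selector
    D = env.water_depth

    # All images within the order implied by the signature.
    vs = []
    max_order = s_want + b_want + 1
    for m in range(-max_order, max_order + 1):
        for sign in (+1, -1):
            if m == 0 and sign == +1:
                continue
            if _bounce_counts(m, sign) == (s_want, b_want):
                vs.append(abs(2 * m * D + sign * tag_depth - receiver_depth))
    if not vs:
        raise ValueError(f"no arrival with bounce signature {arrival_selector}")
    v = min(vs)
    dz = tag_depth - receiver_depth
    L = np.hypot(ranges, v)
    L_direct = np.hypot(ranges, dz)
    return (L - L_direct) / env.sound_speed
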