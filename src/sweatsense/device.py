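"""Discretized sweat-sensing device: layouts, transport and the sensed signal.

A device is a field of collection sites, each at an integer travel distance
``d_travel`` (in transport tiles) from a single volumetric sensor.  Transport
is a pure delay: a droplet released at time ``t`` from a site at distance
``d`` arrives at ``t + d * t_cycle``.  Droplets arriving at the sensor at the
same activation instant merge; the sensor reads the summed volume.

A layout is characterized by a uniform distribution of travel distances: ``k``
distinct distances (the consecutive integers ``1..k`` by default) each
occurring at ``n_collection / k`` sites.  The presets A–G share 5040 sites,
H and I have 10080.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .sweatgen import ReleaseEvent

__all__ = [
    "DeviceLayout",
    "GlandPlacement",
    "SensorEvent",
    "SensorSignal",
    "LAYOUT_PRESETS",
    "build_layout",
    "travel_time",
    "assign_glands",
    "occupancy_check",
    "synthesize_signal",
]

#: Preset layouts: name -> (number of distinct travel distances, occurrences).
#: A–G have 5040 collection sites; H and I have 10080.  C, E and F are chosen
#: as divisors of 5040 interpolating the anchors A=1260, B=144, D=70, G=1;
#: all presets are overridable through ``build_layout``.
LAYOUT_PRESETS: dict[str, tuple[int, int]] = {
    "A": (1260, 4),
    "B": (144, 35),
    "C": (105, 48),
    "D": (70, 72),
    "E": (48, 105),
    "F": (28, 180),
    "G": (1, 5040),
    "H": (140, 72),
    "I": (72, 140),
}

DEFAULT_V_MIN = 0.2  # nL, minimum transportable droplet volume
DEFAULT_N_LEADS = 5  # electrical leads activating every 5th tile (metadata)


@dataclass(frozen=True)
class DeviceLayout:
    """Travel-distance distribution plus device constants."""

    name: str
    distinct_dtravel: tuple[int, ...]  # distinct travel distances, tiles
    occurrences: int  # collection sites per distinct distance
    t_cycle: float  # s, tile activation period
    v_min: float = DEFAULT_V_MIN  # nL
    n_leads: int = DEFAULT_N_LEADS

    def __post_init__(self) -> None:
        if self.t_cycle <= 0:
            raise ValueError(f"t_cycle must be positive, got {self.t_cycle}")
        if self.occurrences < 1:
            raise ValueError("occurrences must be >= 1")
        if len(self.distinct_dtravel) == 0:
            raise ValueError("layout needs at least one travel distance")
        if any(d < 1 or d != int(d) for d in self.distinct_dtravel):
            raise ValueError("travel distances must be positive integers")
        if len(set(self.distinct_dtravel)) != len(self.distinct_dtravel):
            raise ValueError("travel distances must be distinct")

    @property
    def n_collection(self) -> int:
        """Total number of collection sites."""
        return len(self.distinct_dtravel) * self.occurrences

    @property
    def travel_times(self) -> tuple[float, ...]:
        """Distinct travel times in seconds (one per distinct distance)."""
        return tuple(travel_time(d, self.t_cycle) for d in self.distinct_dtravel)

    @property
    def travel_spread(self) -> float:
        """Max minus min travel time, seconds."""
        tts = self.travel_times
        return max(tts) - min(tts)

    def site_dtravel(self, site: int) -> int:
        """Travel distance (tiles) of collection site ``site``.

        Sites are indexed 0..n_collection-1; consecutive blocks of
        ``occurrences`` sites share a distance.
        """
        if not 0 <= site < self.n_collection:
            raise ValueError(f"site index {site} out of range")
        return self.distinct_dtravel[site // self.occurrences]

    def travel_time_differences(self) -> frozenset[int]:
        """All realizable travel-time differences, in activation-grid units.

        The decomposition step constrains the relative arrival offsets of
        candidate gland patterns to this set.
        """
        ds = sorted(set(self.distinct_dtravel))
        return frozenset(b - a for a in ds for b in ds if b >= a)


@dataclass(frozen=True)
class GlandPlacement:
    """Assignment of glands to collection sites (at most one gland per site)."""

    layout: DeviceLayout
    sites: Mapping[int, int]  # gland_id -> collection-site index

    def __post_init__(self) -> None:
        if len(set(self.sites.values())) != len(self.sites):
            raise ValueError("at most one gland per collection site")

    def dtravel(self, gland_id: int) -> int:
        return self.layout.site_dtravel(self.sites[gland_id])

    @property
    def n_glands(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class SensorEvent:
    """One (possibly merged) droplet arrival at the volumetric sensor."""

    time: float  # s
    volume: float  # nL
    gland_ids: tuple[int, ...] = ()  # provenance, for evaluation only


@dataclass(frozen=True)
class SensorSignal:
    """Time-ordered merged droplet arrivals: the sensed pulse train V(t)."""

    events: tuple[SensorEvent, ...]
    t_cycle: float

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sensor event times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([e.volume for e in self.events])

    @property
    def total_volume(self) -> float:
        return float(sum(e.volume for e in self.events))


def build_layout(
    name: str,
    n_collection: int | None = None,
    t_cycle: float = 0.5,
    *,
    v_min: float = DEFAULT_V_MIN,
    n_leads: int = DEFAULT_N_LEADS,
    distinct_dtravel: Sequence[int] | None = None,
    occurrences: int | None = None,
) -> DeviceLayout:
    """Build a preset (A–I) or custom device layout.

    For presets, distinct distances are the consecutive integers ``1..k``.
    A custom layout is specified through ``distinct_dtravel`` and
    ``occurrences`` (``name`` is then just a label).
    """
    if distinct_dtravel is not None:
        if occurrences is None:
            if n_collection is None:
                raise ValueError("custom layout needs occurrences or n_collection")
            occurrences = n_collection // len(distinct_dtravel)
        return DeviceLayout(
            name=name,
            distinct_dtravel=tuple(int(d) for d in distinct_dtravel),
            occurrences=occurrences,
            t_cycle=t_cycle,
            v_min=v_min,
            n_leads=n_leads,
        )
    if name not in LAYOUT_PRESETS:
        raise ValueError(
            f"unknown layout {name!r}; presets are {sorted(LAYOUT_PRESETS)} "
            "(or pass distinct_dtravel for a custom layout)"
        )
    k, occ = LAYOUT_PRESETS[name]
    if n_collection is not None:
        if n_collection % k:
            raise ValueError(f"n_collection={n_collection} not divisible by k={k}")
        occ = n_collection // k
    return DeviceLayout(
        name=name,
        distinct_dtravel=tuple(range(1, k + 1)),
        occurrences=occ,
        t_cycle=t_cycle,
        v_min=v_min,
        n_leads=n_leads,
    )


def travel_time(dtravel: int, t_cycle: float) -> float:
    """Travel time from a collection site to the sensor: dtravel * t_cycle."""
    if dtravel < 1:
        raise ValueError(f"dtravel must be >= 1 tile, got {dtravel}")
    return dtravel * t_cycle


def assign_glands(
    layout: DeviceLayout, n_sg: int, rng: np.random.Generator | int | None = None
) -> GlandPlacement:
    """Place ``n_sg`` glands on distinct collection sites, uniformly at random.

    Deterministic for a fixed seed / generator state.
    """
    if n_sg < 1:
        raise ValueError("n_sg must be >= 1")
    if n_sg > layout.n_collection:
        raise ValueError(
            f"cannot place {n_sg} glands on {layout.n_collection} sites"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sites = rng.choice(layout.n_collection, size=n_sg, replace=False)
    return GlandPlacement(layout=layout, sites={g: int(s) for g, s in enumerate(sites)})


def occupancy_check(
    gland_density: float,
    site_diameter_um: float,
    n_sites: int,
    *,
    max_glands: int = 11,
) -> dict[str, float]:
    """Poisson sizing check for a device design.

    Models active glands as a spatial Poisson process of intensity
    ``gland_density`` (glands/cm^2).  Collection apertures are treated as
    squares of width ``site_diameter_um`` so that the total collection area of
    the canonical design (5000 sites of 100 um) is 0.5 cm^2.  Returns the
    probabilities used to justify the sizing: that the device samples at least
    one gland, that a single site holds at most one gland, and the tail
    probability of more than ``max_glands`` glands over the whole device.
    """
    if gland_density <= 0:
        raise ValueError("gland_density must be positive")
    site_area_cm2 = (site_diameter_um * 1e-4) ** 2
    lam_site = gland_density * site_area_cm2
    lam_total = lam_site * n_sites
    return {
        "lambda_site": lam_site,
        "lambda_total": lam_total,
        "p_at_least_one_gland": float(1.0 - math.exp(-lam_total)),
        "p_site_at_most_one": float(stats.poisson.cdf(1, lam_site)),
        "p_more_than_max": float(stats.poisson.sf(max_glands, lam_total)),
    }


def poisson_pmf(n: int, lam: float) -> float:
    """P(N = n) for a Poisson count: e^-lam lam^n / n!."""
    return float(stats.poisson.pmf(n, lam))


def synthesize_signal(
    layout: DeviceLayout,
    placement: GlandPlacement,
    gland_events: Mapping[int, Sequence[ReleaseEvent]],
) -> SensorSignal:
    """Superpose delayed gland release streams into the sensed pulse train.

    Each release arrives ``travel_time(d_travel)`` later; arrivals at the
    identical activation instant merge by volume summation (ideal transport,
    no losses).  Raises if a gland stream has no placement.
    """
    missing = set(gland_events) - set(placement.sites)
    if missing:
        raise ValueError(f"glands without a collection site: {sorted(missing)}")
    arrivals: dict[int, tuple[float, list[int]]] = {}
    tc = layout.t_cycle
    for gid, events in gland_events.items():
        delay = travel_time(placement.dtravel(gid), tc)
        for ev in events:
            tick = round((ev.time + delay) / tc)
            vol, gids = arrivals.get(tick, (0.0, []))
            arrivals[tick] = (vol + ev.volume, gids + [gid])
    merged = tuple(
        SensorEvent(time=tick * tc, volume=vol, gland_ids=tuple(sorted(gids)))
        for tick, (vol, gids) in sorted(arrivals.items())
    )
    return SensorSignal(events=merged, t_cycle=tc)
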