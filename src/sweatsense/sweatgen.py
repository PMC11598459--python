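"""Pulsatile sweat-gland model: droplet production at a collection site.

Eccrine sweat glands secrete in synchronized bursts: an active period of
``t_ap`` seconds (default 30 s) followed by a resting period of ``t_rp``
seconds (default 150 s).  During an active period a gland produces a volume
``SRg`` (nL per active period) at a constant rate.  The collection site of a
discretized sensing device turns that volume into droplets of the minimum
transportable volume ``v_min``: a droplet detaches once ``v_min`` has
accumulated and leaves the site at the next activation of the transport tile
(every ``t_cycle`` seconds).  Volume short of ``v_min`` at the end of an
active period is carried to the next one as the residual ``v_res``.

The number of droplets in a cycle therefore follows

    N_d = floor((SRg + v_res) / v_min),        v_res' = (SRg + v_res) mod v_min

and the droplet release times form an arithmetic train on the activation
grid: the first droplet leaves at the first activation after ``v_min`` is
reached, subsequent droplets every ``floor_grid(v_min / rate)`` seconds,
where ``rate = SRg / t_ap`` is the secretion rate in nL/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "GlandParams",
    "GlandState",
    "ReleaseEvent",
    "droplet_count",
    "simulate_gland",
    "events_to_frame",
]

#: Duration of one active period, seconds.
DEFAULT_T_AP = 30.0
#: Duration of one resting period, seconds.
DEFAULT_T_RP = 150.0


@dataclass(frozen=True)
class GlandParams:
    """Physiological parameters of a single sweat gland.

    Parameters
    ----------
    srg:
        Sweat volume produced per active period, nL/t_ap.  Physiological
        range for sedentary subjects is roughly 0.4–1 nL per active period.
    t_ap:
        Active-period duration in seconds.
    t_rp:
        Resting-period duration in seconds.
    """

    srg: float
    t_ap: float = DEFAULT_T_AP
    t_rp: float = DEFAULT_T_RP

    def __post_init__(self) -> None:
        if self.srg <= 0:
            raise ValueError(f"srg must be positive, got {self.srg}")
        if self.t_ap <= 0:
            raise ValueError(f"t_ap must be positive, got {self.t_ap}")
        if self.t_rp < 0:
            raise ValueError(f"t_rp must be non-negative, got {self.t_rp}")

    @property
    def rate(self) -> float:
        """Secretion rate during the active period, nL/s."""
        return self.srg / self.t_ap

    @property
    def cycle_period(self) -> float:
        """Duration of one full activity cycle (active + rest), seconds."""
        return self.t_ap + self.t_rp


@dataclass
class GlandState:
    """Mutable per-gland bookkeeping carried across activity cycles."""

    v_res: float = 0.0  # residual volume below v_min at end of a cycle, nL


@dataclass(frozen=True)
class ReleaseEvent:
    """One droplet leaving a collection site."""

    time: float  # seconds from simulation start, multiple of t_cycle
    volume: float  # nL
    gland_id: int
    cycle_index: int


def droplet_count(srg: float, v_res: float, v_min: float) -> int:
    """Number of droplets produced in one active period.

    ``floor((srg + v_res) / v_min)`` where ``srg`` is the volume produced in
    one active period and ``v_res`` the residual carried in from the previous
    one.

    Examples
    --------
    >>> droplet_count(0.4, 0.0, 0.2)
    2
    >>> droplet_count(0.7, 0.1, 0.2)
    4
    """
    if v_min <= 0:
        raise ValueError(f"v_min must be positive, got {v_min}")
    if srg <= 0:
        raise ValueError(f"srg must be positive, got {srg}")
    if not -1e-9 <= v_res < v_min:
        raise ValueError(f"v_res must lie in [0, v_min), got {v_res}")
    v_res = max(v_res, 0.0)
    # guard against float droop (e.g. 0.7+0.1 = 0.7999...) at exact multiples
    return int(math.floor((srg + v_res) / v_min + 1e-9))


def _ceil_grid(t: float, step: float) -> float:
    """Smallest grid multiple of ``step`` that is >= ``t``."""
    return math.ceil(t / step - 1e-9) * step


def _floor_grid(t: float, step: float) -> float:
    return math.floor(t / step + 1e-9) * step


def simulate_gland(
    params: GlandParams,
    n_cycles: int,
    t_cycle: float,
    v_min: float,
    gland_id: int = 0,
    phase: float = 0.0,
    state: GlandState | None = None,
) -> tuple[list[ReleaseEvent], GlandState]:
    """Simulate droplet release over ``n_cycles`` activity cycles.

    All glands share the activation phase (central, synchronized control), so
    ``phase`` is the common start time of the first active period and must be
    a multiple of ``t_cycle``.  Returns the release events and the final
    residual state.

    Release semantics: within a cycle starting at ``t0`` with residual
    ``v_res``, ``N_d = droplet_count(srg, v_res, v_min)`` droplets of volume
    exactly ``v_min`` are released at

        t0 + anchor + k * spacing,   k = 0 .. N_d - 1

    with ``anchor = ceil_grid((v_min - v_res)/rate)`` (first activation at or
    after the first v_min crossing) and ``spacing = floor_grid(v_min/rate)``
    (grid-aligned inter-droplet interval).  The residual
    ``(srg + v_res) mod v_min`` persists through the resting period.
    """
    if t_cycle <= 0:
        raise ValueError(f"t_cycle must be positive, got {t_cycle}")
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    if v_min <= 0:
        raise ValueError(f"v_min must be positive, got {v_min}")
    if abs(phase - round(phase / t_cycle) * t_cycle) > 1e-9:
        raise ValueError("phase must be a multiple of t_cycle")

    state = state or GlandState()
    rate = params.rate
    events: list[ReleaseEvent] = []
    for cycle in range(n_cycles):
        t0 = phase + cycle * params.cycle_period
        n_d = droplet_count(params.srg, state.v_res, v_min)
        if n_d > 0:
            anchor = _ceil_grid((v_min - state.v_res) / rate, t_cycle)
            spacing = max(_floor_grid(v_min / rate, t_cycle), t_cycle)
            for k in range(n_d):
                events.append(
                    ReleaseEvent(
                        time=t0 + anchor + k * spacing,
                        volume=v_min,
                        gland_id=gland_id,
                        cycle_index=cycle,
                    )
                )
        state = GlandState(v_res=(params.srg + state.v_res) - n_d * v_min)
        # numerical hygiene: keep the invariant 0 <= v_res < v_min exact
        if state.v_res < 0 and state.v_res > -1e-9:
            state = GlandState(v_res=0.0)
    return events, state


def events_to_frame(events: Iterable[ReleaseEvent]) -> pd.DataFrame:
    """Tabulate release events as (gland_id, cycle_index, time_s, volume_nL)."""
    return pd.DataFrame(
        [(e.gland_id, e.cycle_index, e.time, e.volume) for e in events],
        columns=["gland_id", "cycle_index", "time_s", "volume_nL"],
    )
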