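"""Scenario simulation sweeps and error-rate evaluation.

A scenario fixes a device layout, cycle time and per-gland sweat rate, then
simulates many 15-minute signals, each produced by a random number of active
glands placed at random collection sites.  The estimator runs on every
activity-cycle window and its deduplicated gland-count candidates are scored
against the ground truth:

    Es = 100 * (# incorrect candidates) / (# candidates)      per window
    error rate = mean of Es over windows,

with a bias-corrected and accelerated (BCa) bootstrap confidence interval on
the mean.  A window with no candidates (failure) scores Es = 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .device import DeviceLayout, assign_glands, build_layout, synthesize_signal
from .estimator import EstimatorBounds, SegmentResult, estimate_signal
from .sweatgen import GlandParams, simulate_gland

__all__ = [
    "ScenarioConfig",
    "ErrorReport",
    "nd_target",
    "srg_for_nd",
    "segment_error",
    "error_rate",
    "simulate_scenario_signal",
    "run_scenario",
]


def nd_target(srg: float, v_min: float) -> float:
    """Long-run mean droplets per active period for a sweat rate: srg/v_min."""
    return srg / v_min


def srg_for_nd(nd: float, v_min: float = 0.2) -> float:
    """Per-gland sweat rate (nL per active period) giving ``nd`` droplets per
    active period on average: nd * v_min."""
    return nd * v_min


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated working condition of the device.

    ``nsg_scheme`` is ``"stratified"`` (equal signal counts per gland number,
    the default reporting mode for per-NSG curves) or ``"uniform"`` (gland
    number drawn uniformly per signal).
    """

    layout: str = "D"
    t_cycle: float = 0.5
    srg: float = 0.4  # nL per active period per gland
    n_signals: int = 2000
    duration_min: float = 15.0
    nsg_scheme: str = "stratified"
    nsg_range: tuple[int, int] = (1, 11)
    seed: int = 0
    v_min: float = 0.2
    t_ap: float = 30.0
    t_rp: float = 150.0
    n_boot: int = 10_000

    @property
    def nd(self) -> float:
        return nd_target(self.srg, self.v_min)

    @property
    def n_cycles(self) -> int:
        return int(self.duration_min * 60.0 // (self.t_ap + self.t_rp))

    def gland_params(self) -> GlandParams:
        return GlandParams(srg=self.srg, t_ap=self.t_ap, t_rp=self.t_rp)

    def build_layout(self) -> DeviceLayout:
        return build_layout(self.layout, t_cycle=self.t_cycle, v_min=self.v_min)


@dataclass(frozen=True)
class ErrorReport:
    """Per-scenario, per-gland-number error rates with bootstrap CIs."""

    config: ScenarioConfig
    segments: pd.DataFrame  # one row per window
    table: pd.DataFrame  # one row per true gland number

    @property
    def overall_error_rate(self) -> float:
        return float(self.segments["es"].mean())

    def average_error(self, nsg_lo: int = 2, nsg_hi: int = 11) -> float:
        """Mean of the per-NSG error rates over a gland-number range."""
        sub = self.table[(self.table.nsg >= nsg_lo) & (self.table.nsg <= nsg_hi)]
        return float(sub["error_rate_pct"].mean())

    @property
    def failure_rate(self) -> float:
        return float((self.segments["status"] == "failure").mean())


def segment_error(result: SegmentResult, true_nsg: int) -> float:
    """Per-window percentage error over the deduplicated candidate list.

    100 * (# candidates != truth) / (# candidates); an empty candidate list
    (failure) scores 100 (no correct estimation).
    """
    cands = result.nsg_candidates
    if not cands:
        return 100.0
    return 100.0 * sum(c != true_nsg for c in cands) / len(cands)


def error_rate(
    errors: np.ndarray | list[float],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Mean per-window error with a two-sided BCa bootstrap interval.

    All-identical samples yield a degenerate interval equal to the point
    value.
    """
    x = np.asarray(errors, dtype=float)
    if x.size == 0:
        raise ValueError("error_rate needs at least one segment")
    m = float(x.mean())
    if x.size == 1 or np.all(x == x[0]):
        return m, (m, m)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.bootstrap(
            (x,),
            np.mean,
            n_resamples=n_boot,
            confidence_level=1 - alpha,
            method="BCa",
            rng=rng,
        )
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    # BCa degenerates when the jackknife acceleration is undefined
    if not np.isfinite(lo):
        lo = m
    if not np.isfinite(hi):
        hi = m
    return m, (min(lo, m), max(hi, m))


def simulate_scenario_signal(
    layout: DeviceLayout,
    n_sg: int,
    params: GlandParams,
    n_cycles: int,
    rng: np.random.Generator,
):
    """Simulate one multi-gland signal: placement, release trains, transport.

    Returns the sensed signal and the placement (ground truth).
    """
    placement = assign_glands(layout, n_sg, rng)
    gland_events = {
        gid: simulate_gland(params, n_cycles, layout.t_cycle, layout.v_min, gland_id=gid)[0]
        for gid in placement.sites
    }
    return synthesize_signal(layout, placement, gland_events), placement


def _nsg_sequence(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.nsg_range
    if cfg.nsg_scheme == "stratified":
        reps = int(np.ceil(cfg.n_signals / (hi - lo + 1)))
        seq = np.tile(np.arange(lo, hi + 1), reps)[: cfg.n_signals]
        rng.shuffle(seq)
        return seq
    if cfg.nsg_scheme == "uniform":
        return rng.integers(lo, hi + 1, size=cfg.n_signals)
    raise ValueError(f"unknown nsg_scheme {cfg.nsg_scheme!r}")


def run_scenario(
    cfg: ScenarioConfig, bounds: EstimatorBounds | None = None
) -> ErrorReport:
    """Simulate and score one scenario; fully reproducible from its seed.

    A layout whose segmentation is infeasible (travel-time spread reaching
    the activity-cycle period) is reported with failure rate 100% rather than
    aborting.
    """
    bounds = bounds or EstimatorBounds(t_ap=cfg.t_ap)
    layout = cfg.build_layout()
    params = cfg.gland_params()
    root = np.random.SeedSequence(cfg.seed)
    nsg_rng = np.random.default_rng(root.spawn(1)[0])
    nsg_seq = _nsg_sequence(cfg, nsg_rng)
    signal_seeds = root.spawn(cfg.n_signals)

    rows = []
    for i, (n_sg, ss) in enumerate(zip(nsg_seq, signal_seeds)):
        rng = np.random.default_rng(ss)
        signal, _ = simulate_scenario_signal(layout, int(n_sg), params, cfg.n_cycles, rng)
        results = estimate_signal(
            signal, layout, params, bounds, expected_segments=cfg.n_cycles
        )
        for j, res in enumerate(results):
            rows.append(
                {
                    "signal": i,
                    "segment": j,
                    "nsg": int(n_sg),
                    "es": segment_error(res, int(n_sg)),
                    "status": res.status,
                    "failure_stage": res.failure_stage or "",
                    "type1": 1 in res.ambiguity_types,
                    "type2": 2 in res.ambiguity_types,
                    "type3": 3 in res.ambiguity_types,
                    "n_candidates": len(res.nsg_candidates),
                }
            )
    segs = pd.DataFrame(rows)

    boot_rng = np.random.default_rng(root.spawn(2)[1])
    table_rows = []
    for n_sg, grp in segs.groupby("nsg"):
        rate, (lo, hi) = error_rate(grp["es"].to_numpy(), n_boot=cfg.n_boot, rng=boot_rng)
        table_rows.append(
            {
                "layout": cfg.layout,
                "t_cycle": cfg.t_cycle,
                "nd": cfg.nd,
                "nsg": int(n_sg),
                "n_segments": len(grp),
                "error_rate_pct": rate,
                "ci_lo": lo,
                "ci_hi": hi,
                "freq_type1": float(grp["type1"].mean()),
                "freq_type2": float(grp["type2"].mean()),
                "freq_type3": float(grp["type3"].mean()),
                "freq_failure": float((grp["status"] == "failure").mean()),
            }
        )
    table = pd.DataFrame(table_rows).sort_values("nsg").reset_index(drop=True)
    return ErrorReport(config=cfg, segments=segs, table=table)


def plot_error_vs_nsg(reports, ax=None, label_by: str = "layout"):
    """Error rate versus number of active glands, one line per report."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for rep in np.atleast_1d(reports):
        t = rep.table
        label = f"{getattr(rep.config, label_by)}"
        ax.errorbar(
            t["nsg"],
            t["error_rate_pct"],
            yerr=[t["error_rate_pct"] - t["ci_lo"], t["ci_hi"] - t["error_rate_pct"]],
            marker="o",
            capsize=2,
            label=label,
        )
    ax.set_xlabel("number of active sweat glands $N_{SG}$")
    ax.set_ylabel("error rate [%]")
    ax.legend()
    return ax
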