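"""Estimation of the number of active sweat glands from a sensed pulse train.

The estimator inverts the generative model in three steps:

1. **Segmentation** — cut the signal into windows, one per activity cycle.
   A window lasts at most the active-period duration plus the layout's
   travel-time spread; if that cap reaches the activity-cycle period the
   windows of consecutive cycles necessarily overlap and segmentation is
   infeasible for the layout (raises :class:`SegmentationInfeasibleError`).
2. **Quantization** — recover the non-merged droplet volume.  Every sensed
   pulse is an integer multiple of the unknown unit volume ``Vsg``; all unit
   volumes in the admissible range ``[v_min, v_upper)`` that divide every
   pulse volume are enumerated.  More than one admissible unit volume is a
   type-1 ambiguity; none is a quantization failure.
3. **Decomposition** — exhaustively explain the integer pulse train as a
   superposition of per-gland patterns, each an evenly spaced droplet train
   ``(dt_travel offset, dt_droplet spacing, n_d droplets)``.  Synchronized
   glands with a common sweat rate produce identical trains, so the search
   runs over the ``(dt_droplet, n_d)`` grid; candidate spacings are the time
   differences between the window's first and later pulses up to half the
   active period, and pattern offsets must be realizable travel-time
   differences of the layout.  All exact decompositions are enumerated;
   several distinct gland counts are a type-2/3 ambiguity and an empty
   solution list a failure.

All timing arithmetic is carried out in integer activation-grid ticks, so
"exact match" is exact and free of floating-point drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .device import DeviceLayout, SensorEvent, SensorSignal
from .sweatgen import GlandParams

__all__ = [
    "EstimatorBounds",
    "Segment",
    "QuantizedSegment",
    "GlandPattern",
    "Decomposition",
    "SegmentResult",
    "SegmentationInfeasibleError",
    "segment_signal",
    "quantize_segment",
    "candidate_intervals",
    "decompose_segment",
    "estimate_segment",
    "estimate_signal",
    "classify_ambiguity",
]


class SegmentationInfeasibleError(RuntimeError):
    """Windows of consecutive activity cycles necessarily overlap."""


@dataclass(frozen=True)
class EstimatorBounds:
    """Search-space boundaries for the exhaustive decomposition.

    ``nd`` and ``dt_droplet`` bounds jointly enforce at least two droplets
    per active period per gland and at most one droplet per tile activation;
    for a given spacing the admissible droplet counts are further tied to
    the secretion rate the spacing implies (see :func:`nd_range`).
    """

    max_glands: int = 11
    nd_min: int = 2
    nd_max: int = 120
    t_ap: float = 30.0
    quant_rel_tol: float = 1e-6
    #: admissible non-merged volume range is [v_min, v_upper_factor * v_min):
    #: a droplet leaves at most one activation period after crossing v_min
    #: and cannot gain another full v_min while waiting, whatever the rate.
    v_upper_factor: float = 2.0

    @property
    def dt_droplet_max(self) -> float:
        """Largest admissible inter-droplet interval: half the active period."""
        return self.t_ap / 2.0

    def v_upper(self, v_min: float) -> float:
        """Upper bound (exclusive) on the non-merged droplet volume."""
        return self.v_upper_factor * v_min

    def nd_range(self, spacing: float, t_cycle: float) -> tuple[int, int]:
        """Admissible droplet counts for a train of the given spacing (s).

        A gland secretes throughout its active period, so its droplet count
        and spacing both express the same secretion rate: a spacing observed
        on the activation grid corresponds to a continuous inter-droplet
        interval in ``[spacing, spacing + t_cycle)``, hence to
        ``floor(t_ap / (spacing + t_cycle)) .. floor(t_ap / spacing) + 1``
        droplets per active period (the +1 admits the residual-volume
        droplet and applies only when the spacing does not divide the active
        period exactly, since an exact division leaves no residual),
        intersected with the global ``[nd_min, nd_max]`` bounds.
        """
        lo = max(self.nd_min, int(self.t_ap / (spacing + t_cycle)))
        ratio = self.t_ap / spacing
        hi = int(ratio) if abs(ratio - round(ratio)) < 1e-9 else int(ratio) + 1
        return lo, min(self.nd_max, hi)


@dataclass(frozen=True)
class Segment:
    """One window of the sensed signal, covering a single activity cycle."""

    start: float  # s, time of first event in the window
    end: float  # s, time of last event in the window
    events: tuple[SensorEvent, ...]
    t_cycle: float

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events)

    @property
    def volumes(self) -> tuple[float, ...]:
        return tuple(e.volume for e in self.events)

    @property
    def ticks(self) -> tuple[int, ...]:
        """Event times in activation-grid ticks, relative to the first event."""
        t0 = self.events[0].time
        return tuple(round((e.time - t0) / self.t_cycle) for e in self.events)


@dataclass(frozen=True)
class QuantizedSegment:
    """A segment with one admissible unit volume and integer multiplicities."""

    segment: Segment
    v_hat: float  # estimated non-merged droplet volume, nL
    multiplicities: tuple[int, ...]  # per event, >= 1

    @property
    def ticks(self) -> tuple[int, ...]:
        return self.segment.ticks

    @property
    def total_droplets(self) -> int:
        return sum(self.multiplicities)


@dataclass(frozen=True)
class GlandPattern:
    """One gland's droplet train within a window (times relative to the
    window's first pulse, seconds)."""

    dt_travel: float  # anchor offset, s
    dt_droplet: float  # inter-droplet spacing, s
    n_d: int  # droplets in the train


@dataclass(frozen=True)
class Decomposition:
    """One exact explanation of a quantized window."""

    patterns: tuple[GlandPattern, ...]

    @property
    def n_sg(self) -> int:
        return len(self.patterns)

    @property
    def spacings(self) -> frozenset[float]:
        return frozenset(p.dt_droplet for p in self.patterns)

    @property
    def nd_by_spacing(self) -> tuple[tuple[float, tuple[int, ...]], ...]:
        by: dict[float, list[int]] = {}
        for p in self.patterns:
            by.setdefault(p.dt_droplet, []).append(p.n_d)
        return tuple(sorted((s, tuple(sorted(nds))) for s, nds in by.items()))


@dataclass(frozen=True)
class SegmentResult:
    """Deduplicated gland-count candidates for one window."""

    nsg_candidates: tuple[int, ...]  # sorted, distinct
    status: str  # "unique" | "ambiguous" | "failure"
    ambiguity_types: frozenset[int] = frozenset()
    failure_stage: str | None = None  # "segmentation" | "quantization" | "decomposition"
    quantizations: tuple[QuantizedSegment, ...] = ()
    decompositions: tuple[Decomposition, ...] = ()


def segmentation_window_cap(layout: DeviceLayout, timing: GlandParams) -> float:
    """Maximum window duration: active period + travel-time spread (+ one
    activation period of slack for a droplet released just after the active
    period ends)."""
    return timing.t_ap + layout.travel_spread + layout.t_cycle


def segment_signal(
    signal: SensorSignal, layout: DeviceLayout, timing: GlandParams | None = None
) -> list[Segment]:
    """Cut the sensed signal into one window per activity cycle.

    A window opens at the first arrival after the previous window closed and
    accepts events for at most the window cap.  Raises
    :class:`SegmentationInfeasibleError` when the cap reaches the activity
    cycle period, in which case droplets from consecutive active periods
    interleave and no correct windowing exists.
    """
    timing = timing or GlandParams(srg=1.0)
    if len(signal.events) == 0:
        return []
    cap = segmentation_window_cap(layout, timing)
    if cap >= timing.cycle_period:
        raise SegmentationInfeasibleError(
            f"window cap {cap:.2f} s >= activity cycle {timing.cycle_period:.2f} s "
            f"for layout {layout.name} at t_cycle={layout.t_cycle} s"
        )
    segments: list[Segment] = []
    window: list[SensorEvent] = []
    for ev in signal.events:
        if window and ev.time - window[0].time > cap:
            segments.append(
                Segment(window[0].time, window[-1].time, tuple(window), signal.t_cycle)
            )
            window = []
        window.append(ev)
    segments.append(
        Segment(window[0].time, window[-1].time, tuple(window), signal.t_cycle)
    )
    return segments


def quantize_segment(
    segment: Segment,
    v_min: float,
    v_upper: float | None = None,
    *,
    bounds: EstimatorBounds | None = None,
    rel_tol: float | None = None,
) -> list[QuantizedSegment]:
    """Enumerate admissible non-merged droplet volumes for a window.

    A unit volume ``v`` in ``[v_min, v_upper)`` is admissible when every
    sensed pulse volume is an integer multiple of ``v`` within ``rel_tol``.
    Candidates are the divisors ``V_smallest / m`` of the smallest pulse; the
    reported ``v_hat`` is the least-squares refinement over all pulses.  An
    empty list is a quantization failure; more than one entry marks a type-1
    ambiguity.
    """
    bounds = bounds or EstimatorBounds()
    if v_upper is None:
        v_upper = bounds.v_upper(v_min)
    rel_tol = bounds.quant_rel_tol if rel_tol is None else rel_tol
    vols = segment.volumes
    if any(v < v_min * (1 - rel_tol) for v in vols):
        raise ValueError("event volume below the minimum transportable volume")
    v_small = min(vols)
    out: list[QuantizedSegment] = []
    seen: set[tuple[int, ...]] = set()
    for m in range(1, int(math.floor(v_small / v_min * (1 + rel_tol))) + 1):
        v = v_small / m
        if not (v_min * (1 - rel_tol) <= v < v_upper * (1 - rel_tol)):
            continue
        mult: list[int] = []
        for vol in vols:
            r = vol / v
            k = round(r)
            if k < 1 or abs(r - k) > rel_tol * r:
                break
            mult.append(k)
        else:
            key = tuple(mult)
            if key in seen:
                continue
            seen.add(key)
            # least-squares refinement of the unit volume given multiplicities
            v_hat = sum(vol * k for vol, k in zip(vols, mult)) / sum(
                k * k for k in mult
            )
            out.append(
                QuantizedSegment(segment=segment, v_hat=v_hat, multiplicities=key)
            )
    return out


def candidate_intervals(
    quantized: QuantizedSegment | Segment,
    t_ap: float = 30.0,
    t_cycle: float | None = None,
) -> list[float]:
    """Candidate inter-droplet intervals for the decomposition search.

    The time differences between the window's first pulse and every later
    pulse, kept when they lie in ``[t_cycle, t_ap / 2]`` (at least two
    droplets per active period, at most one droplet per tile activation).
    """
    segment = quantized.segment if isinstance(quantized, QuantizedSegment) else quantized
    t_cycle = segment.t_cycle if t_cycle is None else t_cycle
    t0 = segment.events[0].time
    eps = 1e-9
    return [
        e.time - t0
        for e in segment.events[1:]
        if t_cycle - eps <= e.time - t0 <= t_ap / 2 + eps
    ]


def decompose_segment(
    quantized: QuantizedSegment,
    layout: DeviceLayout,
    bounds: EstimatorBounds | None = None,
) -> list[Decomposition]:
    """Enumerate all exact decompositions of a quantized window.

    All active glands secrete at the same (unknown) rate under synchronized
    central control, so within one decomposition every pattern shares the
    inter-droplet spacing, and each pattern's droplet count must be
    rate-consistent with that spacing (:meth:`EstimatorBounds.nd_range`).
    For every candidate spacing from :func:`candidate_intervals`, the pulse
    train is tiled by backtracking: the earliest unexplained pulse must be
    the first droplet of a new pattern (patterns are causal and identical in
    spacing), so it anchors a train whose length runs over the admissible
    droplet counts; multiplicities are subtracted and the search recurses,
    memoizing residuals.  A decomposition is emitted when the residual is
    exactly zero and all boundaries hold:

    - at most ``max_glands`` patterns,
    - spacing within ``[t_cycle, t_ap / 2]``, droplet counts admissible for
      the spacing,
    - every anchor offset realizable as a travel-time difference of the
      layout.

    Solutions are deduplicated by their multiset of ``(dt_droplet, n_d)``
    pattern parameters — the quantities that determine the gland count and
    the ambiguity type — each reported with one concrete set of anchor
    offsets.
    """
    bounds = bounds or EstimatorBounds()
    tc = quantized.segment.t_cycle
    ticks = quantized.ticks
    n = len(ticks)
    index_of = {t: i for i, t in enumerate(ticks)}

    spacings_s = candidate_intervals(quantized, t_ap=bounds.t_ap, t_cycle=tc)
    spacings = sorted({round(s / tc) for s in spacings_s})
    allowed_offsets = layout.travel_time_differences()
    max_glands = bounds.max_glands
    counts = list(quantized.multiplicities)
    total = sum(counts)

    solutions: dict[tuple, tuple] = {}
    for s in spacings:
        nd_lo, nd_hi = bounds.nd_range(s * tc, tc)
        if nd_lo > nd_hi or total < nd_lo:
            continue
        # memo: (residual suffix, gland budget) ->
        #   {sorted lengths of a completing suffix: witness [(anchor, L), ..]}
        memo: dict[tuple[bytes, int], dict[tuple, tuple]] = {}

        def solve(glands_left: int) -> dict[tuple, tuple]:
            i0 = 0
            while i0 < n and counts[i0] == 0:
                i0 += 1
            if i0 == n:
                return {(): ()}
            rem = counts[i0:]
            # bounds: a pattern covers each instant once, nd_hi pulses at most
            if (
                glands_left == 0
                or max(rem) > glands_left
                or sum(rem) > glands_left * nd_hi
            ):
                return {}
            key = (bytes(rem), glands_left)
            cached = memo.get(key)
            if cached is not None:
                return cached
            out: dict[tuple, tuple] = {}
            anchor = ticks[i0]
            if anchor in allowed_offsets:
                # longest run of open pulses from the anchor at this spacing
                run = [i0]
                t = anchor + s
                while (
                    len(run) < nd_hi
                    and t in index_of
                    and counts[index_of[t]] > 0
                ):
                    run.append(index_of[t])
                    t += s
                for length in range(nd_lo, len(run) + 1):
                    for i in run[:length]:
                        counts[i] -= 1
                    for sub_lengths, sub_witness in solve(glands_left - 1).items():
                        lengths = tuple(sorted(sub_lengths + (length,)))
                        if lengths not in out:
                            out[lengths] = ((anchor, length),) + sub_witness
                    for i in run[:length]:
                        counts[i] += 1
            memo[key] = out
            return out

        for lengths, witness in solve(max_glands).items():
            key = (s, lengths)
            if key not in solutions:
                solutions[key] = witness

    return sorted(
        (
            Decomposition(
                patterns=tuple(
                    GlandPattern(dt_travel=a * tc, dt_droplet=s * tc, n_d=L)
                    for a, L in sorted(witness)
                )
            )
            for (s, _lengths), witness in solutions.items()
        ),
        key=lambda d: (
            d.n_sg,
            tuple((p.dt_droplet, p.n_d, p.dt_travel) for p in d.patterns),
        ),
    )


def classify_ambiguity(
    quantizations: tuple[QuantizedSegment, ...] | list[QuantizedSegment],
    decompositions: tuple[Decomposition, ...] | list[Decomposition],
) -> frozenset[int]:
    """Ambiguity types present among the solutions of one window.

    Type 1: several admissible unit volumes (ambiguous quantization).
    Type 2: two decompositions share their spacing set but allocate the
    droplets into different trains (ambiguous ``n_d``).
    Type 3: two decompositions differ in their spacing sets (ambiguous
    ``dt_droplet``).
    """
    types: set[int] = set()
    if len(quantizations) > 1:
        types.add(1)
    for i, da in enumerate(decompositions):
        for db in decompositions[i + 1 :]:
            if da.spacings == db.spacings:
                if da.nd_by_spacing != db.nd_by_spacing or da.n_sg != db.n_sg:
                    types.add(2)
            else:
                types.add(3)
    return frozenset(types)


def estimate_segment(
    segment: Segment,
    layout: DeviceLayout,
    bounds: EstimatorBounds | None = None,
) -> SegmentResult:
    """Run quantization and decomposition on one window and collect the
    deduplicated gland-count candidates with their ambiguity types."""
    bounds = bounds or EstimatorBounds()
    quantizations = tuple(quantize_segment(segment, layout.v_min, bounds=bounds))
    if not quantizations:
        return SegmentResult(
            nsg_candidates=(), status="failure", failure_stage="quantization"
        )
    decomps: list[Decomposition] = []
    for q in quantizations:
        decomps.extend(decompose_segment(q, layout, bounds))
    if not decomps:
        return SegmentResult(
            nsg_candidates=(),
            status="failure",
            failure_stage="decomposition",
            quantizations=quantizations,
        )
    nsg = tuple(sorted({d.n_sg for d in decomps}))
    types = classify_ambiguity(quantizations, decomps)
    status = "ambiguous" if (len(nsg) > 1 or types) else "unique"
    return SegmentResult(
        nsg_candidates=nsg,
        status=status,
        ambiguity_types=types,
        quantizations=quantizations,
        decompositions=tuple(decomps),
    )


def estimate_signal(
    signal: SensorSignal,
    layout: DeviceLayout,
    timing: GlandParams | None = None,
    bounds: EstimatorBounds | None = None,
    expected_segments: int | None = None,
) -> list[SegmentResult]:
    """Full pipeline on one signal: segmentation, then per-window estimation.

    When segmentation is infeasible for the layout, every expected window is
    reported as a segmentation failure instead of raising.
    """
    timing = timing or GlandParams(srg=1.0)
    try:
        segments = segment_signal(signal, layout, timing)
    except SegmentationInfeasibleError:
        n = expected_segments if expected_segments is not None else 1
        return [
            SegmentResult(
                nsg_candidates=(), status="failure", failure_stage="segmentation"
            )
            for _ in range(n)
        ]
    return [estimate_segment(seg, layout, bounds) for seg in segments]
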