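# Methods

`sweatsense` simulates sweat collection by a discretized (droplet-based)
sweat-sensing device and estimates, from the sensed volume pulse train alone,
how many sweat glands produced it.  The gland count is what turns a total
sweat rate into a *per-gland* sweat rate, the quantity that biomarker
concentrations in sweat actually depend on.

## Sweat generation model

Eccrine glands secrete in synchronized bursts under central control: an
active period of `t_AP` (default 30 s) followed by a resting period `t_RP`
(default 150 s), one activity cycle of 3 min.  Every active gland secretes
the same volume `SRg` per active period (0.4–1 nL/t_AP in the sedentary
range) at a constant rate `SRg/t_AP`, and all glands share the activation
phase.  These are deliberate idealizations; inter-gland rate variability,
desynchronized activation and variable period durations are out of scope.

A collection site discretizes this volume into droplets of the minimum
transportable volume `V_min` (default 0.2 nL).  Per cycle the droplet count
follows the floor recurrence

    N_d = floor((SRg + V_res) / V_min),    V_res' = (SRg + V_res) mod V_min

where `V_res` is the sub-droplet residual carried across cycles.  At
`SRg = 0.7` nL/t_AP this alternates 3, 4, 3, 4 droplets (reported as
`N_d = 3.5` droplets/t_AP).  Release times form an exact arithmetic train on
the tile-activation grid (period `t_cycle`): the first droplet leaves at the
first activation at or after the `V_min` crossing,
`anchor = ceil_grid((V_min − V_res)/rate)`, subsequent droplets every
`spacing = floor_grid(V_min/rate)`.

Two properties of this formulation are load-bearing.  First, droplet volumes
are exactly `V_min`, which keeps the count recurrence and volume
conservation exact (`Σ volumes + V_res = n_cycles · SRg` to 1e−9 nL).  An
alternative in which each droplet carries the full volume accumulated up to
its release instant (including the grid overshoot) breaks the alternation —
at 0.7 nL/t_AP and `t_cycle = 0.5` s it yields 3, 3, 4 droplets (mean 10/3) —
and is inconsistent with the residual recurrence.  Second, release times are
*exactly* evenly spaced within a cycle.  The estimator matches integer pulse
trains exactly; a generator with per-droplet grid jitter would make the true
pattern unrecoverable by construction.  The grid-flooring of the spacing
means a droplet can leave up to one activation before its continuous-time
`V_min` crossing; at all sweat rates whose crossing interval is a grid
multiple (all sweat rates used in the bundled scenarios at `t_cycle = 0.5` s) the two
formulations coincide.

## Device model

A layout is a uniform distribution of travel distances: `k` distinct
distances, each at `N_collection / k` sites.  Distances are the consecutive
integers `1..k` (configurable).  Presets: A = 1260×4, B = 144×35, C = 105×48,
D = 70×72, E = 48×105, F = 28×180, G = 1×5040 (5040 sites), H = 140×72,
I = 72×140 (10080 sites).  C, E, F are interpolating divisors of 5040
between the documented anchors; all are overridable.  Transport is a pure
deterministic delay `t_travel = d_travel · t_cycle` (the five-lead activation
scheme is retained as metadata only); droplets arriving at the same
activation instant merge by volume summation.  Glands are placed uniformly
at random on distinct sites (at most one gland per site, justified by a
Poisson occupancy calculation exposed as `occupancy_check`; note the Poisson
tail beyond 11 glands at mean 5 is ≈0.5%, which the check reports as
computed).

## Estimation algorithm

Three steps per signal:

1. **Segmentation.** Windows of at most
   `t_AP + (max − min travel time) + t_cycle`, opened at the first arrival
   after the previous window closes.  If the cap reaches the cycle period
   (`t_AP + t_RP`), windows of consecutive cycles necessarily overlap and
   the signal is reported as a segmentation failure.  With consecutive
   integer distances, layout A's spread (1259 tiles) exceeds the resting
   period at every cycle time in 0.25–0.75 s, so layout A is infeasible
   throughout, not only at 0.75 s; its travel-distance set can be narrowed in
   configuration to explore intermediate regimes.
2. **Quantization.** Every sensed pulse is an integer multiple of the
   unknown non-merged droplet volume.  Admissible unit volumes lie in
   `[V_min, 2 V_min)` — the rate-agnostic bound: a droplet leaves at most one
   activation after crossing `V_min` and cannot gain a full `V_min` while
   waiting.  Candidates are the divisors `V_smallest/m` of the smallest
   pulse, kept if every pulse divides to an integer within relative
   tolerance 1e−6 (exact in the noiseless model; the divisor enumeration
   replaces a grid search with identical results).  Several admissible unit
   volumes are a type-1 ambiguity; none is a quantization failure.
3. **Decomposition.** Exhaustive explanation of the quantized train as a
   superposition of per-gland droplet trains `(Δt_travel, Δt_droplet, N_d)`.
   Two structural constraints follow from the generative model:
   *shared spacing* — all glands secrete at the same rate, so all patterns
   in one decomposition share `Δt_droplet`; and *rate consistency* — a
   spacing `s` implies a secretion rate, hence
   `N_d ∈ [floor(t_AP/(s+t_cycle)), floor(t_AP/s) + 1]`, the `+1` (the
   residual-volume droplet) only when `s` does not divide `t_AP` exactly.
   Candidate spacings are the time differences between the window's first
   and later pulses within `[t_cycle, t_AP/2]`; pattern anchor offsets must
   be realizable travel-time differences of the layout; at most 11 patterns.
   For each spacing, the earliest unexplained pulse must anchor a new
   pattern, so the search backtracks only over pattern lengths, memoizing
   residual states and bounding by the remaining gland budget.  Solutions
   are deduplicated by their `(spacing, droplet-count multiset)` — the
   quantities that determine the estimated gland count and the ambiguity
   type — each with one concrete anchor witness.  Without the two structural
   constraints the enumeration is exponential (minutes per window at high
   sweat rates) and admits cross-gland reinterpretations that push
   low/medium-rate error rates far above every reported bound.

Ambiguity typing over the pooled solutions: type 1 — several admissible unit
volumes; type 2 — equal spacing sets, different droplet allocations;
type 3 — different spacing sets.  A window's error is
`Es = 100 · (#candidates ≠ truth) / #candidates` over the deduplicated
candidate list, 100 for an empty list; a scenario's error rate is the mean
`Es` with a two-sided 95% BCa bootstrap interval (scipy implementation,
default 1e4 replicates, configurable up to 1e5; degenerate samples collapse
the interval onto the point estimate).

## Scenario scales and defaults

Scenario defaults follow the simulated working conditions: 15-minute signals (5 activity
cycles), gland counts 1–11 (stratified equally per count for per-count
curves; a uniform-random mode is available), 2000 signals per scenario at
full scale.  The bundled acceptance runs and tests use 200 signals per
scenario (1000 windows, ≥90 per gland count), which resolves error rates of
a few tenths of a percent; per-window estimation costs ~1–20 ms, so a
scenario runs in seconds on one core.

## Known limitations

- **High sweat rates at high gland counts.** In this exact-volume model a
  window is ambiguous only if an exact alternative tiling exists.  At
  `N_d ∈ {4, 5}` the halved-rate reinterpretation doubles the gland count,
  so beyond ~5 true glands it exceeds the 11-gland cap and most windows
  become uniquely decodable: per-count error falls to ~0 instead of staying
  above the 50% floor that holds for 1–5 glands (exactly 50% in the
  single-gland case).  We could not find a search rule that keeps the floor
  at high counts without simultaneously destroying the low/medium-rate
  accuracy; the two regimes appear to require a noisier generative model
  (e.g. per-droplet volume overshoot) than the idealized one used here.
- **Residual cross-gland pairing at medium rate.** Two glands whose
  travel-time difference falls in 10–15 s admit an exact alternative that
  pairs their corresponding droplets into 2-droplet trains, producing a
  genuine ambiguity peak of ~5–15% at 2 glands (and smaller high-count
  analogues).  This keeps best-layout averages at ~0.3–1.3% rather than
  below 0.2%.
- **Layout G (single travel time).** All droplets merge exactly; merged
  volumes remain exact multiples of `V_min`, so quantization returns one or
  a few admissible unit volumes rather than failing outright; high gland
  counts yield heavily ambiguous (not failed) windows.  A quantization
  *failure* (no admissible unit volume) requires inconsistent volumes, which
  the noiseless generator cannot produce.
- Sensor noise, transport losses, droplet collisions on shared tracks and
  stochastic gland variability are intentionally not modeled; passing tests
  demonstrate algorithmic identifiability under the idealized model, not
  robustness on real devices.
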