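# Methods

`howlloc` estimates the 2-D positions of vocalising animals (canid howls in
particular) from the arrival times of the same sound at three or more
GPS-synchronised autonomous recorders, and provides the survey analyses that
surround that estimate: accuracy against known source positions, detection
distances, event structure, and array-spacing design. This note documents
the model, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Localisation model

A howl emitted at unknown position *s* and unknown time *t₀* arrives at
recorder *i* (position *rᵢ*) at

    tᵢ = t₀ + |s − rᵢ| / c,

with *c* the speed of sound. Differencing against the earliest-arrival
(reference) recorder eliminates *t₀*: each time difference of arrival
(TDOA) Δtᵢ = tᵢ − t_ref constrains *s* to one branch of a hyperbola with
the two recorders as foci. The estimate minimises the sum of squared TDOA
residuals

    J(s) = Σᵢ [ (|s − rᵢ| − |s − r_ref|)/c − Δtᵢ ]².

Assumptions: flat terrain (2-D geometry; altitude unmodelled), homogeneous
and windless atmosphere (single *c*), perfectly synchronised clocks (GPS
time), and arrival-marking errors that are independent across recorders.
Three recorders give an exactly determined problem; four or more
over-determine it and average the marking noise down.

### Solver

`J` is smooth but multimodal: with exactly three recorders the two
hyperbola branches can intersect at two points with near-zero residual.
Closed-form TDOA solutions do not expose both candidates cleanly, so the
solver enumerates basins explicitly:

1. **Coarse grid** (default 50 m cell) over the contributing recorders'
   bounding box padded by `max_range` (default 4 km, generous relative to
   the longest plausible non-detection distances). `J` is evaluated
   vectorised on every node.
2. **Refinement**: the best `n_refine` (default 3) mutually well-separated
   cells seed derivative-free Nelder–Mead polishing (`xatol` 1e-4 m).
3. **Selection**: lowest RMS residual wins; a second minimum that is far
   (> 2 grid cells) from the winner yet fits essentially as well is an
   unresolved hyperbola ambiguity — the candidate nearer the recorder
   centroid is reported as primary, the other as `alternate`, and the
   result is flagged `ambiguous`.

A result is `converged` when the RMS residual falls below `residual_tol`
(default 1e-6 s) or the refinement stalls at a proper minimum. Arrays whose
centred coordinates have a smallest singular value below 1 m are rejected
as collinear: the TDOA problem is then degenerate in 2-D.

Grid-then-refine is deliberately conservative. The test suite checks it
against an exhaustive 1 m grid search re-evaluating `J` at every node: the
refined objective must never exceed the exhaustive minimum.

### Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `c` | 343 | m/s | dry air at ~20 °C; helper `speed_of_sound(T) = 331.3 + 0.606·T`. Field protocols rarely log temperature, so `c` is configurable; a 5% error in `c` scales positions by roughly the same factor. |
| `grid_cell` | 50 | m | coarse enough to keep the grid ~10⁴–10⁵ nodes, fine enough that every residual basin of a ≥800 m array contains a node. |
| `max_range` | 4000 | m | howls are audible but rarely markable much beyond ~2.5 km; 4 km keeps out-of-hull sources inside the search box. |
| `residual_tol` | 1e-6 | s | ~0.3 mm of path at 343 m/s; effectively "exact fit". |
| `max_tdoa_window` | 15 | s | ~5 km of path difference; a wider spread means salient points from different howls were joined under one id. |
| `min_recorders` | 3 | — | the geometric minimum for 2-D multilateration. |

## Geodesy

All solver geometry runs in a local equirectangular frame: metres per
degree fixed at the projection origin, with the longitude scale reduced by
cos(lat). Over a ≤10 km survey area this agrees with spherical geodesics
to better than 0.1%, and it makes distances reproducible bit-for-bit. The
meridian constant is 111 320 m/° (40 075 km circumference / 360). Ground
distances between WGS84 points use the same formula with the scale taken
at the midpoint latitude, rounded to whole metres for reporting — the
precision of 5-decimal coordinates (~1.1 m per least digit) makes ±2 m the
honest comparison tolerance for any distance recomputed from printed
coordinates. Points on the convex-hull boundary classify as *inside*;
classification is invariant to the (affine) change between local frames,
so the choice of projection origin cannot flip a flag.

## Event grouping

Howls are grouped into events by the one-minute silence rule: a gap of
≥ 60 s between consecutive howls starts a new event. Gaps are measured
start-to-start because howl end times are not modelled; with howls a few
seconds long and a 60 s threshold the two conventions assign identically
in practice. Grouping sorts internally, so it is order-independent and
idempotent.

## Detection-distance analysis

For each howl, distances are measured from its position to every recorder
active at its time, split into detections (salient point markable) and
non-detections. Positions follow the asymmetric field convention: true
locations for howls elicited at surveyed points, estimated locations for
wild howls (no truth exists) — which biases wild-howl distances by the
localisation error, typically tens of metres against km-scale distances.
Detection status is an *input* (it encodes an annotator's judgement), never
inferred from audio. The summary reports the pooled mean detection
distance, the per-howl maximum averaged, and the count of non-detections
closer than the same howl's furthest detection — the overlap statistic
that drives spacing recommendations. Note the pooled mean weights howls by
their detection count, so it is not bounded by the averaged per-howl
maximum; the guaranteed inequality (asserted as a property test) is
against the mean of per-howl means.

## Synthetic surveys

The generator produces the structure the analysis assumes, not audio:

- **Arrays**: sequential rejection placement until every recorder's nearest
  neighbour lies in [800, 1200] m (configurable), matching the random-walk
  way arrays are laid out in the field; near-collinear layouts are
  rejected.
- **Sources**: uniform over the array's convex hull (optionally buffered
  outward), grouped into events whose internal gaps are 5–45 s and whose
  separations exceed 60 s, so the silence rule recovers the event structure
  exactly. Defaults (10 recorders, 27 howls, 7 events, one week) mirror a
  realistic short deployment.
- **Arrivals**: the forward model above plus independent Gaussian jitter,
  sd 0.05 s by default — the accuracy with which a careful annotator can
  pin a salient point on a spectrogram.
- **Detection**: probability p(d) = p_max / (1 + (d/d50)^k), defaults
  p_max = 0.95, d50 = 1200 m, k = 4. This is a smooth stand-in chosen so
  that detections beyond 2 km *and* non-detections under 1 km both occur
  with non-trivial probability — the overlap regime real surveys show. No
  published detection function exists for this setting; the curve is a
  modelling choice, not an estimate.

Everything is reproducible: one `numpy` generator seeded per scenario
drives placement, detection draws and jitter.

What the generator does **not** emulate: wind, temperature gradients and
habitat attenuation (which make real detection anisotropic and
time-varying), clock drift or recorder failure, howl directionality, chorus
overlap that confuses salient-point matching, and annotator bias that
correlates marking errors across recorders. Passing tests therefore show
the *pipeline* is correct under its stated noise model; they do not show
that 50 ms is the right jitter for any particular habitat, nor predict
field accuracy beyond order of magnitude.

### Problem sizes

Validation uses deliberately modest Monte-Carlo sizes chosen for tight,
deterministic tests: 10–20 sources per jitter level for the degradation
check, 20 seeded scenarios for solver-vs-exhaustive-grid equivalence, 1000
random cases for hull classification, and ~20 replicates per spacing for
the design curve. The design-curve function accepts `n_reps ≥ 100` for
publication-quality estimates; the monotonicity assertions here need only
the coarse contrast between sub-km and multi-km spacings.

## Known limitations

- 2-D only; elevation differences shorten apparent horizontal distances.
- A single sound speed for all recorder paths; heterogeneity enters the
  estimate as correlated TDOA error the model cannot absorb.
- No error ellipses or credible regions — point estimates with RMS
  residual only, matching what the downstream analyses consume.
- The three-recorder case is exactly determined: residuals are ~0 even
  when the geometry is ambiguous, so the `ambiguous` flag (not the
  residual) is the quality signal there.
- Estimates outside the local hull are retained but flagged: hyperbola
  geometry degrades quickly outside the array, and roughly half of real
  localisations land there.
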