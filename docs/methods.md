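# Methods

## Problem and data model

The package quantifies directed collective migration of bilateral
cardiomyocyte populations converging at the embryonic midline during
zebrafish cardiac fusion. Input is a long-format track table: one row
per tracked object per timepoint, with 3D position (μm), frame index,
embryo, left/right side and cell class. Each embryo additionally carries
exactly one *reference* track (the notochord tip) used for drift
correction. The coordinate convention is fixed: x is the medial-lateral
axis, y the anterior-posterior axis (+y anterior), z the imaging depth.
Time alignment across embryos is by frame index, since all timelapses
start at an equivalent developmental stage.

Only *complete* tracks — a position at every frame from 0 to the
embryo's last frame — enter the analysis; incomplete tracks are dropped
entirely rather than interpolated, and the filter reports retained and
dropped counts per embryo.

## Preprocessing

**Drift correction.** The reference track's cumulative displacement
from frame 0 to frame k is subtracted from every cell position at frame
k (positions, not velocities, are corrected; frame-0 positions are
unchanged). This anchoring at frame 0 is equivalent to per-step velocity
subtraction for complete tracks and is robustly defined. Any
displacement field shared by reference and cells — stage or imaging
drift — is cancelled exactly. The landmark itself retracts slightly
posteriorly; it nevertheless *defines* the analysis frame, and that
biological motion is deliberately not modelled out (all AP velocities
are therefore relative to the landmark).

**Side alignment.** With a declared midline at `x = m` (metadata
supplied by the simulator or the user — the midline is an anatomical
landmark, not a quantity fit from the tracks), the medial coordinate is
`xm = x − m` for left-side cells and `m − x` for right-side cells, so
movement toward the midline strictly increases `xm` on both sides. All
downstream kinematics are invariant under reflection of the embryo
about the midline with side labels swapped.

**AP bands.** Within each embryo and side, cells are ranked by initial
y (most anterior first, ties broken by track id) and split into
top/middle/bottom bands of balanced size; when the count is not
divisible by three, the spare cells go to the outer bands (top first),
so two cells yield top + bottom with an empty middle. Bands are fixed
at the first frame.

## Per-cell kinematics

All metrics are computed in the XY plane only (Z motion is negligible
in this system), from the sampled polygonal trajectory with no
smoothing, over each complete track of duration `T`:

| metric | definition | units |
|---|---|---|
| path length | Σ step lengths ("distance") | μm |
| displacement | start→end chord | μm |
| speed | path length / T | μm/min |
| efficiency | displacement / path length | — (∈ [0, 1]) |
| velocity_ml | Δxm / T (+ = medial) | μm/min |
| velocity_ap | Δy / T (+ = anterior) | μm/min |
| direction | atan2(\|Δy\|, Δxm), degrees | [0°, 180°] |

A single-argument arctangent of |Δy|/Δxm cannot distinguish medial from
lateral movement when Δxm < 0; the quadrant-aware two-argument form
maps lateral movement to (90°, 180°], which is exactly the sector that
separates misdirected mutant cells in the angular histogram. Direction
uses |Δy|, so all metrics except the sign of velocity_ap are invariant
under an AP flip, and direction < 90° ⇔ velocity_ml > 0. Stationary
tracks get speed 0 with efficiency and direction reported as *missing*
(not 0), so they cannot bias cohort means; their count is logged.

## Aggregation and statistics

Two levels are exposed because both are informative: cohort-level
per-cell means (cells as replicates) and per-embryo means of cell
metrics (embryos as replicates, revealing e.g. a mild/severe phenotype
split). Published cohort velocities are treated as per-cell means,
consistent with their framing as averages over individual cells; the
per-embryo alternative is available from the same summaries.

"No medial movement" is operationalised as `velocity_ml ≤ 0` (no
threshold is stated in the source material; 0 is the natural boundary
and equivalent to direction ≥ 90°). The direction histogram uses 10
equal 18° bins over [0°, 180°], right-open except the last bin, which
is closed so that 0° and 180° both count; counts conserve the number of
cells with defined direction.

Group comparison is the two-tailed unpaired Student's t-test in its
classic pooled-variance form (df = nₐ + n_b − 2); "Student's t-test"
is taken at its historical meaning rather than Welch's variant, which
is available via `variant="welch"`. No multiple-testing correction is
applied, matching the analysis the package reproduces. Degenerate
inputs (n < 2, or zero pooled variance with equal means) raise rather
than returning a meaningless statistic.

## Bilateral-domain gap

Convergence of the bilateral heart-field domains is summarised per
embryo and stage from their medial-edge curves (sampled x(y) profiles
supplied as coordinates; image segmentation is out of scope): the
left-right distance is evaluated by linear interpolation at three AP
positions spaced 200 μm apart and the **maximum** of the three is the
representative gap — sensitive to a convergence failure anywhere along
the field, not only at its narrowest point. The anchor of the three
points is not specified by the source procedure; the default centres
them on the midpoint of the two curves' common AP span, with anterior
anchoring as an option. The statistic is invariant to side swap and
midline reflection and monotone under pointwise widening. Per-stage
group comparison reuses the pooled t-test; stages with fewer than two
embryos in a group are skipped with a warning.

## Synthetic cohorts and calibration

No tracking data were released for the cohorts of interest, so the
generator reproduces their statistical structure. Cells follow a biased
random walk: per frame (Δt = 4 min), displacement =
deterministic drift + embryo-coherent noise + per-cell noise + imaging
drift. Gaussian increments are chosen for analytic tractability of the
recovery tests — the estimator of mean medial velocity is then exactly
unbiased. The coherent component draws one shared XY increment per
embryo per frame, carrying a fraction `coherent_fraction` of the step
variance; with full coherence, cells on a side never exchange
medial-lateral rank order, emulating the observed collective movement
without neighbour exchange. Defaults, with rationale:

| parameter | default | rationale |
|---|---|---|
| dt | 4 min | imaging cadence of the emulated timelapses |
| n_timepoints | 31 (120 min) | inside the emulated 2–3 h window |
| noise_sigma | 0.3 μm/step/axis | convention; puts per-cell speeds in a plausible 0.2–0.4 μm/min range (per-cell noise magnitudes are not published) |
| coherent_fraction | 0.5 | convention; visibly collective but not lock-step |
| z_noise_sigma | 0.05 μm/step | cells move negligibly in depth |
| initial_gap | 100 μm | bilateral populations ~100 μm apart at the starting stage |
| ap_drift | 0.05 μm/min | small anterior bias; AP velocity does not differ between groups |
| reference_retraction | 0.05 μm/min | "slight" posterior landmark retraction |
| imaging_drift | (0.15, −0.1) μm/min | nonzero so drift correction is exercised end to end |

Each embryo contributes 20–30 tracked cells split between two medial
columns per side, plus one reference track sharing the imaging drift.
Per-embryo random streams derive from (cohort seed, CRC32 of the embryo
id), so an embryo's trajectories are reproducible independently of the
rest of the cohort.

**Calibrated presets.** The wild-type preset has 8 embryos × 21 cells =
168 cells, with per-embryo drifts 0.19 ± {0.01…0.05} μm/min chosen to
sum to the target exactly (all positive, spread comparable to observed
inter-embryo variability). The mutant preset has 6 embryos, 137 cells:
2 mild embryos (23 cells each) at the wild-type mean drift 0.19, and 4
severe embryos (23, 23, 23, 22 cells) sharing a single drift `d` solved
in closed form from the cell-weighted cohort-mean constraint

    (n_mild · 0.19 + n_severe · d) / 137 = 0.016
    ⇒ d = (137·0.016 − 46·0.19) / 91 ≈ −0.0720 μm/min,

i.e. slightly below zero, consistent with severe embryos having lost
medial movement. A single shared severe value is the simplest model
honouring that description. Because the walk's increments have zero
mean, the pipeline's cohort-mean velocity estimator is unbiased, and
with noise off it recovers each embryo's drift to machine precision.

**What the generator does not emulate.** Real cardiomyocytes move as an
epithelial sheet with spatially structured neighbour relations, possible
AP-position-dependent phenotypes (mild mutants lose medial movement
anteriorly first), pauses in acquisition, and tracking errors. Passing
recovery tests therefore demonstrates the correctness of the analysis
chain — drift handling, alignment, metric definitions, aggregation —
under the assumed motion statistics, not the biological fidelity of the
walk itself.

## Problem sizes and numerics

Simulated cohorts use the preset sizes throughout (168/137 cells, 31
frames); the acceptance script averages 20 independent replicate seeds
per cohort, giving a standard error of the recovered cohort mean of
about 0.002 μm/min for the wild-type cohort and below that for the
mutant. Floating-point conventions: exactness claims in the tests are
asserted at machine precision (≤1e-12 relative); histogram binning
relies on numpy's half-open bins with a closed final edge; AP-band ties
break by track id; direction and efficiency of zero-length tracks are
NaN by design and excluded from means.

## Known limitations

* Translation-only drift correction via a single landmark; no rotation
  or scaling registration.
* The t-test treats cells as independent within cohorts at the per-cell
  level; embryo-level coherent motion violates this mildly (the
  per-embryo level is provided for conservative inference, and a
  mixed-effects treatment is out of scope).
* The Imaris-style reader targets a generic position/time/track export;
  vendor schemas vary and may need header synonyms added.
* Incomplete tracks are dropped, never imputed; with heavy dropout this
  can bias toward trackable (slower, brighter) cells, as in any
  complete-track analysis.
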