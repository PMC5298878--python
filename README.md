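# cardiofuse

Quantification of directed cardiomyocyte movement during cardiac fusion.

During zebrafish heart development, two bilateral populations of
cardiomyocytes migrate toward the embryonic midline and merge into a
single cardiac ring. Timelapse tracking of these cells — in wild-type
embryos and in *pdgfra* loss-of-function (*ref*) mutants whose cells lose
their medial heading — produces long-format track tables. `cardiofuse`
implements the downstream analysis of such tables for developmental
biologists quantifying directed collective migration:

* **drift correction** against a per-embryo reference landmark (the
  notochord tip): the landmark's cumulative displacement from the first
  frame is subtracted from every cell position, removing stage/imaging
  drift shared by all objects;
* **left/right alignment** into a common medial coordinate
  `xm` (for a declared midline at `x = m`: `xm = x − m` on the left,
  `m − x` on the right), so movement toward the midline is positive on
  both sides;
* **per-cell kinematics** over each complete track of duration `T`:
  path length `L = Σᵢ‖pᵢ₊₁ − pᵢ‖` ("distance"), chord
  `D = ‖p_end − p_start‖` ("displacement"), speed `L/T`, efficiency
  index `D/L ∈ [0, 1]`, axis velocities `Δxm/T` (medial-lateral) and
  `Δy/T` (anterior-posterior), and net direction
  `θ = atan2(|Δy|, Δxm) ∈ [0°, 180°]` (0° purely medial, 90° purely
  AP, 180° purely lateral) — all in the XY plane;
* **aggregation and testing**: per-embryo means, cohort per-cell means,
  the fraction of cells with no medial movement (`Δxm/T ≤ 0`), a 10-bin
  angular (rose) histogram of net directions, and two-tailed unpaired
  pooled-variance Student's t-tests between groups;
* the **bilateral-domain gap statistic**: the distance between the
  medial edges of the two heart-field domains sampled at three
  anterior-posterior points 200 μm apart, keeping the maximum as the
  representative gap per embryo and stage, compared between groups per
  stage;
* a **calibrated synthetic-trajectory generator** (biased random walk
  with an embryo-level coherent component) whose wild-type preset
  (8 embryos, 168 cells) and mutant preset (6 embryos, 137 cells;
  2 mild + 4 severe) reproduce the published cohort-mean medial-lateral
  velocities of 0.19 and 0.016 μm/min.

## Worked example

```python
import cardiofuse as cf

# simulate the two calibrated cohorts
wt = cf.simulate_cohort("wt", seed=1)
mut = cf.simulate_cohort("ref_mutant", seed=1)
print(wt.n_tracks, mut.n_tracks)

def analyze(tt):
    tt, _ = cf.filter_complete_tracks(tt)
    tt = cf.align_sides(cf.drift_correct(tt))
    return cf.compute_kinematics(tt)

kin_wt, kin_mut = analyze(wt), analyze(mut)
print(f"wt  mean ML velocity: {kin_wt['velocity_ml'].mean():.4f} um/min")
print(f"mut mean ML velocity: {kin_mut['velocity_ml'].mean():.4f} um/min")
print(f"non-medial fraction:  wt {cf.fraction_non_medial(kin_wt):.2f}, "
      f"mut {cf.fraction_non_medial(kin_mut):.2f}")
cmp = cf.compare_groups(kin_wt["velocity_ml"], kin_mut["velocity_ml"])
print(f"t = {cmp.t_statistic:.2f}, p = {cmp.p_value:.2e}")
```

prints

```
168 137
wt  mean ML velocity: 0.1881 um/min
mut mean ML velocity: 0.0188 um/min
non-medial fraction:  wt 0.00, mut 0.66
t = 16.60, p = 1.81e-44
```

That is: the wild-type cohort moves medially at ≈0.19 μm/min while the
mutant cohort is near zero on average (two of its six embryos behave
like wild type, the other four have lost medial movement, and two thirds
of mutant cells show no medial movement at all); the per-cell difference
between cohorts is highly significant.

The same pipeline is available from the shell:

```sh
cardiofuse simulate --preset wt --seed 1 --outdir out
cardiofuse simulate --preset ref_mutant --seed 1 --outdir out
cardiofuse analyze --tracks out/wt_tracks.csv \
                   --tracks out/ref_mutant_tracks.csv --outdir out/analysis
```

which writes per-cell metrics, per-embryo summaries, cohort means, the
direction histogram, group comparisons and a rose-plot figure, each CSV
carrying a provenance header with the seed and config hash.

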