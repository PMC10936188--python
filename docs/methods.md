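# Methods

This note documents the models, defaults, and design choices behind
`qsip18o`, and what the synthetic-data validation does and does not show.

## Estimation chain

1. **Filtering.** OTUs contributing less than `min_frac` (default 5×10⁻⁵,
   i.e. 0.005%) of all sequences are discarded; the grand total is computed
   before any removal and the comparison keeps taxa exactly at the
   threshold. An OTU must then be present (count > 0) in at least
   `min_reps` (default 2) of the replicates of a treatment × isotope-label
   group; the pipeline requires a taxon to pass in both the ¹⁶O and the ¹⁸O
   group of the treatment under analysis, because both arms are needed to
   compute its density shift. Replicates are the resampling unit of the
   bootstrap, which is why prevalence is judged within these groups.
2. **Recovery adjustment.** DNA is lost between loading a gradient and
   recovering its fractions. For each sample, recovery = Σ_f
   (copies/µL)_f·volume_f divided by the unfractionated qPCR total; every
   fraction's absolute copies are divided by this single per-sample ratio,
   so adjusted copies sum to the unfractionated total exactly. A truly
   per-fraction efficiency is not identifiable from these inputs (one
   equation per sample), so a per-sample ratio is the implemented model;
   recovery > 1 is kept with a warning since it indicates qPCR calibration
   offset rather than impossible physics.
3. **Density window.** Fractions with buoyant density in the closed
   interval [1.69, 1.74] g/mL are retained by default — the window where
   essentially all DNA bands in field CsCl gradients. Recovery is computed
   before windowing (it concerns the whole gradient). For simulated
   experiments the window is set to cover the full density grid
   (1.60–1.85), since simulated bands may legitimately extend past the
   field default and truncating them would bias the validation.
4. **Weighted density, EAF, rates.** As in the README. Weighted densities
   use per-fraction relative abundances (computed over all sequenced taxa
   of each fraction library) multiplied by recovery-adjusted absolute
   copies; a switch (`weight_by_copies=False`) reverts to relative
   abundances alone — the two coincide when fraction totals are equal.
   W_light per taxon is the mean over the ¹⁶O replicates in which the taxon
   appears. Negative EAF point estimates are reported as-is; only the CI
   rule decides activity.

### Numerical safeguards

* GC inferred outside [0, 1] is clamped with a warning (possible under
  noise for extreme densities).
* The estimator-level unlabeled pool is clipped into (0, min(N_t, N₀)]
  before logs, enforcing b ≥ 0 and d ≤ 0 under noise while keeping
  r = b + d exact (the clip cancels in the sum). An apparent complete
  turnover (unlabeled pool ≤ 0) leaves b and d undefined rather than
  infinite.
* Taxa undetected at t₀ but present at t_end get N₀ floored at one copy
  equivalent and are flagged (`n0_floored`) instead of dropped.
* The pure function `per_capita_rates` applies the textbook formulas
  without clamping and raises on invalid inputs; the clamps live only in
  the pipeline estimator.

## Bootstrap

Percentile bootstrap over replicate labels, `n_boot` = 1000, α = 0.05.
Each resample draws the ¹⁸O replicate set and the ¹⁶O replicate set
independently with replacement ("joint" scheme), so uncertainty in the
light-gradient density propagates into the EAF interval; time-zero
measurements follow the ¹⁸O draw because both belong to the same field
replicate. A "labeled-only" scheme (fixed ¹⁶O mean) is available. BCa-type
corrections are deliberately not used: with three replicates the
higher-order terms are unstable, and percentile intervals are the common
qSIP practice.

Known limitation: with n = 3 replicates the percentile bootstrap is
systematically narrow (theoretical coverage ~0.80–0.85 for mean-type
statistics), and sequencing shot noise adds a small positive EAF bias for
unlabeled taxa (a stray read of a taxon in a heavy fraction is multiplied
by the large adjusted copy number that labeled taxa moved there). Both
effects are intrinsic to the assay and the prescribed interval method, not
artifacts of this implementation — the noise-free chain recovers truth to
~10⁻⁵. Consequently measured CI coverage is ≈0.79–0.82 rather than the
nominal 0.95, and the false-positive active-call rate can exceed the
nominal 5%; interpret activity calls for weakly labeled taxa accordingly.

## Synthetic-data generator

The generator emulates the post-QC measurement chain, with defaults chosen
to represent the study conditions it stands in for:

* **Community.** Lognormal absolute abundances, ln N₀ ~ Normal(µ=10, σ=1).
  σ = 1 represents the abundance-filtered community core that survives the
  0.005% filter (field studies analyze a few hundred such OTUs), not the
  full rank-abundance curve of soil. GC ~ Uniform(0.3, 0.7); b ~
  Uniform(0.05, 0.6) day⁻¹, d ~ Uniform(−0.6, −0.1) day⁻¹ (magnitudes
  bracketing reported soil community rates); a configurable fraction of
  taxa gets b = 0 to provide ground-truth-negative taxa.
* **Consistency of label and rates.** Under the estimator's model the
  taxon-level EAF is tied to reproduction: EAF = (1 − e^(−b·t))·(1 −
  0.002000429). `simulate_community` derives `true_eaf` from `b_true` so
  both the EAF and the rate round trips can hold simultaneously. The
  simulator splits each taxon's final copies into an unlabeled pool at the
  GC-determined density and a labeled pool at the maximum-labeling density,
  using the same density↔molecular-weight maps the estimator inverts; when
  a requested EAF exceeds the two-pool ceiling (1 − natural abundance), the
  pool mass is raised instead so the mixture centroid always sits at the
  density implied by the requested EAF.
* **Measurement.** Gaussian band spreading (σ = 0.006 g/mL) over a
  20-fraction grid spanning 1.640–1.800 g/mL (mass beyond the grid is
  truncated with a warning); per-fraction multinomial sequencing at
  `seq_depth` = 50 000 reads per library (each fraction and each
  unfractionated t₀ sample is its own library); per-fraction qPCR with
  mean-one lognormal noise at CV 0.1; unfractionated totals as the mean of
  three technical qPCR replicates at the same CV (standard practice for the
  measurements that anchor absolute abundances); a per-sample recovery loss
  drawn from Uniform(0.6, 0.95). `exact=True` switches off all measurement
  noise for oracle checks; the recovery loss remains and is inverted
  exactly.
* **What it does not emulate:** read-level artifacts (chimeras, primer
  bias), 16S copy-number variation between taxa, DNA-extraction bias,
  compositional coupling between taxa beyond the shared multinomial, lag
  phases or non-exponential growth, and nucleotide recycling (which in real
  data biases reproduction estimates downward). Passing round-trip tests
  therefore demonstrates correctness of the inference algebra and its noise
  robustness, not immunity to these biological confounders.

## CUE module

Two-pool linear isotope mixing for the new-DNA fraction, isolated in one
function so a variant (e.g. a fixed fraction of DNA oxygen derived from
water) can be substituted; the correction factor `water_o_fraction`
defaults to 1.0 (all DNA oxygen from water). The soil-water atom fraction
is computed from the labeling protocol (default: 400 µL of 98 atom% water
added to 2 g dry soil at 20% gravimetric moisture → 0.491) rather than
hard-coded. Respiration is expressed as ng C/g soil/h (24-h CO₂
accumulation divided by 24). Conversion factors from DNA to microbial
biomass C are sample-specific inputs; synthetic values (≈40 ng C per ng
DNA) are used in tests.

## Problem sizes

Validation runs use 20 taxa (noise-free round trip), 200 taxa (noisy
parameter recovery), and 500 taxa with 1000 bootstrap resamples
(calibration); each completes in seconds because the bootstrap is
vectorized over taxa × resamples. Larger communities scale linearly in
taxa and resamples.
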