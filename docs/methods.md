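# Methods

This note documents the models, estimators, and design choices behind
`cycledecay`, and what the synthetic benchmarks do and do not demonstrate
about real data.

## Cell-cycle time from FUCCI fluorescence

The FUCCI-G1 reporter (mKO2-hCdt1) accumulates monotonically through G1,
so its level indexes time since division. Calibration proceeds in the
units of the experiment:

* **Trace alignment and clipping.** Live-imaging traces are aligned at the
  metaphase-to-anaphase transition (t = 0, defined by the abrupt drop of
  the FUCCI-G2 signal). The G2 channel carries bleed-through from the G1
  reporter under 488 nm excitation; 31% of the G1 intensity is subtracted
  before any use of the G2 channel (`crosstalk_fraction = 0.31`). Traces
  are clipped at the end of G1, detected as the point where the mean
  corrected G2 signal exceeds a configurable fraction (default 5%) of its
  range — an explicit parameter in place of a by-eye threshold.
* **Polynomial calibration.** The mean clipped trace, normalized to the
  mean early-S-phase G1 intensity, is fit by least squares to a cubic
  `p(t)`. The cubic has no mechanistic meaning; it is a smooth, invertible
  description of the data. The fit must be strictly increasing on the
  observed span, which is verified, and the fit is rejected otherwise.
* **Early-S normalization.** Early-S cells are gated as G2 intensity
  within [2.5%, 10%] of the G2 range and G1 intensity above 2.5% of the G1
  range (literal min–max range by default; a 0.5–99.5 percentile option
  guards against FACS outliers). Because the early-S mean G1 level is
  stable, dividing by it puts microscopy and FACS intensities on one
  dimensionless scale, making the calibration transferable between
  instruments. Scaling all intensities of a snapshot by any constant
  leaves assigned times unchanged.
* **Inversion and flags.** Per cell, `p(t) = normalized intensity` is
  solved by bracketed root finding (tolerance 10⁻⁶ min). Intensities
  outside `[p(t_min), p(t_max)]` clamp to the range ends with
  `clamped_low`/`clamped_high` flags rather than extrapolating the cubic —
  extrapolated cubics lose monotonicity, so clamping fails safe. Times
  past a confidence horizon (default 300 min) are kept but flagged
  `low_confidence`, reflecting the growing cell-to-cell spread of reporter
  levels later in G1.
* **Timing uncertainty.** At every trace time point the mean ± 1 SD
  intensities are pushed through the inverse calibration; the average
  absolute time offset of the two is the timing SD. It is zero for
  heterogeneity-free traces and grows with amplitude CV; on a locally
  linear stretch it reduces to (intensity SD)/(slope).

With 20% multiplicative amplitude heterogeneity, time assignment has a
hard ceiling: even a perfectly linear calibration cannot exceed a Spearman
rank correlation of ~0.95 between inferred and true times for ages uniform
on 0–540 min. The synthetic benchmark asserts ρ > 0.90.

## QC and normalization

Cells with fewer than 5900 or more than 111,000 total UMIs are removed
(low-quality wells and doublets; bounds inclusive — only strict violations
are discarded). Note the protocol literature writes the upper bound with a
European thousands separator ("111.000"); it is 111,000 UMIs.

Size factors default to cell total over the geometric mean of totals, so
mean log size factor is zero; a median-of-ratios scheme is selectable.
Library-size factors absorb both capture-efficiency variation and the
2-fold mRNA content drop at division, which is the intended behaviour:
expression is analyzed per recovered transcriptome. A consequence worth
knowing: any genuine global content change over G1 (e.g. when the decaying
panel is a large fraction of the library) is also absorbed, slightly
flattening normalized trajectories. In study-like panels where stable
genes dominate (>80% of counts), the distortion is a few percent.

Gene detection requires a mean raw count ≥ 2 over G2/M cells in *every*
plate. Averaging over G2/M cells — not all cells — keeps the filter from
discarding genes precisely because they are downregulated in G1. Raw
counts are used (the natural reading of a reads threshold).

## Differential expression

For each detected gene, counts from G2/M cells and G1 cells of the first
4 h are modelled as NB with log link,
`log E[y] = log(sf) + b0 + b1·group`, and the group term is tested by
likelihood ratio against the intercept-only model (χ², 1 df). Analyses of this kind often
delegate the comparison to a trajectory-inference package; this is an
independent NB-GLM implementation, so list-level equality with any such
pipeline's calls is not claimed.

Two estimator choices matter:

* **Dispersion.** The NB dispersion α (var = μ + αμ²) is estimated by
  method of moments per gene. Estimating it on the pooled G1 window is
  wrong for exactly the genes of interest: their *temporal decline inside
  the window* would be counted as dispersion, roughly doubling α and
  halving the test's z. The default therefore estimates α on the G2/M
  cells alone — a flat reference population at a single nominal time —
  and moderates the per-gene estimate halfway toward the panel median to
  damp moment-estimator noise at ~100 cells (the familiar shrinkage idea
  from bulk RNA-seq dispersion estimation). Under the null both choices
  coincide, so type-I calibration is unaffected (verified at 0.03–0.07
  empirical error at nominal 0.05 over 1000 simulated null genes).
* **Fold change.** The classification fold change compares G2/M cells with
  G1 cells from the late part of the DE window (default 180–240 min),
  emulating a trajectory-endpoint contrast. A plain window-mean ratio
  cannot reach 2-fold for delayed-wave genes — a gene that is flat for the
  first 80 min and then decays with a ~60-min half-life averages ~0.67 of
  its G2/M level over 0–240 min even though its level at 4 h is ~4-fold
  down — so the window mean would structurally exclude the delayed wave.
  A pseudocount of 0.1 keeps ratios finite on sparse genes while barely
  perturbing detected genes (mean ≥ 2).

Genes are called down/up at fold change ≤ 1/2 (≥ 2) and p ≤ 0.05/#genes.
With 86 G2/M reference cells the two-group contrast has an intrinsic power
ceiling: planted delayed-wave genes are recovered at ~85%, immediate-wave
genes at ~100%, with essentially no false discoveries at the Bonferroni
threshold. A Wilcoxon rank-sum fallback is available for robustness
checks.

## Wave detection

Per downregulated gene, normalized expression vs time (G2/M cells at a
nominal −10 min so the mitotic-exit decline is anchored on both sides) is
fit with a penalized cubic smoothing spline; cells sharing a time point
are averaged with multiplicity weights. The spline's first derivative on a
1-min grid gives the decline profile; it is normalized so its minimum is
exactly −1, and `t_cross` is the first grid time at which it reaches
−0.95. `t_max_decline` is the derivative argmin.

* **Smoothing.** Generalized cross-validation remains the function-level
  default, and is appropriate for smooth, low-noise profiles (it
  interpolates noiseless input to machine precision). For per-cell NB
  noise, however, GCV optimizes *function* estimation and undersmooths the
  *derivative*; crossing times then scatter by ±30 min and the two waves
  blur together. The pipeline default is a strong fixed penalty
  (`spline_lam = 1e7`, with minutes on the x-axis and multiplicity
  weights), under which slope profiles are stable, mitotic-exit declines
  collapse onto the first time point — as expected for the immediate
  wave — and planted waves are re-identified at ≥ 95%. The smoother is
  linear, so fixed-λ fits remain exactly scale- and shift-equivariant.
* **Classification.** Default `window` mode: immediate iff `t_cross` is
  within 50 min of metaphase — the midpoint of the two wave times (within
  ~20 min of metaphase vs ~80 min into G1), which tolerates the ±15–30 min
  spread of crossing estimates under count noise. A stricter `first_point`
  mode (immediate iff the crossing is at the very first grid time) is
  available and behaves well only under strong smoothing.

## Decay kinetics

The two-phase model: constant `m0` until `t_onset`, then
`dm/dt = mu − gamma·m`, i.e. relaxation to `mu/gamma` with rate `gamma`;
the model is continuous at the onset. Fitting is a grid search over
`t_onset ∈ {0, 10, …, 370}` min; at each onset, bounded trust-region least
squares over (m0, mu, gamma) with bounds γ ∈ (10⁻⁵, 1] min⁻¹ (half-lives
from ~0.7 min to ~48 days), μ ≥ 0, m0 > 0. Initialization: m0 from the
pre-onset mean (earliest decile if no cell precedes the onset), γ = ln2/60,
μ = γ × latest-decile mean; three perturbed restarts before flagging
non-convergence. The SSE over all cells selects the onset; ties within
10⁻⁹ relative resolve to the earliest onset. Unweighted per-cell SSE is
the default (plain SSE is the model's stated selection criterion); an
inverse-variance option exists. Half-life = ln 2/γ; genes whose fitted
drop is under 5% of m0 or whose γ pins the lower bound are flagged
non-decaying.

G2/M cells carry no FUCCI-derived time; they are placed at a nominal
−10 min so they constrain `m0` for every onset including `t_onset = 0`.

**Recovery under study conditions.** With NB dispersion 0.3, capture CV
20%, 86 + 750 cells, and a decaying panel of median ~20 counts/cell:
median relative error of γ is ~10%, and the estimated median half-life is
within ~5–10% of the planted median. Onset localization is noisier: the
SSE-argmin estimator has an error SD of ~14 min for a median-abundance
gene even with perfect normalization, so the fraction of genes whose onset
lands within ±10 min (one grid step) is ~0.65 over a heterogeneous
cohort — a noise floor of the estimator at these counts, not an optimizer
artifact (inverse-variance weighting and sub-grid interpolation of the SSE
profile gain only a few points). Wave *membership* from the fitted onsets
is far more robust (~95% correct with a mode-midpoint boundary), because
it only asks which side of 45–50 min an onset falls on.

Transcription ratios (for labeled/unlabeled transcript tables in the
scEU-seq style) are per-gene means of labeled counts over G1 cells divided
by G2 cells; genes with a zero G2 mean are marked excluded rather than
given an infinite ratio.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design with known ground truth:

* 3 plates (round-robin), 86 G2/M + 755 G1 cells with ages uniform on
  0–540 min, 50 early-S snapshot cells for the normalization gate, and
  opt-in QC spike-ins (default 20 low-UMI + 10 high-UMI wells) so the
  filter has true positives and negatives.
* ~3985 genes: 110 + 110 decaying genes with onset modes at ~10 min
  (SD 5) and ~80 min (SD 10), half-lives log-normal with median 60 min
  (σ = 0.25), steady states at 3–15% of m0 (all planted genes fall ≥2-fold,
  mirroring a screen that selects for ≥2-fold declines); stable genes
  log-normal around 5 counts so the stable background dominates the
  library, as in real data. Decaying genes are log-normal around 20
  counts (σ = 0.7).
* NB counts with var = μ + 0.3μ² and log-normal per-cell capture
  efficiency (CV 20%); dispersion below 10⁻⁸ falls back to Poisson.
* FUCCI-G1 traces: per-cell amplitude × (1 − e^(−t/τ)) with τ = 720 min —
  a near-linear, mildly concave rise chosen to match a reporter that
  increases monotonically through 6–8 h and supports accurate timing over
  the first ~5 h — plus Gaussian measurement noise; the raw G2 channel
  includes the 31% crosstalk so the correction stage is exercised. FACS
  intensities are the same quantity at a different instrument gain.

Not emulated: read-level artifacts (UMI collisions, ambient RNA), doublet
transcriptome mixing (doublets appear only as high totals), G0 entry,
transcription bursting, and gene–gene correlation. Passing synthetic
benchmarks therefore demonstrates the estimators' correctness and their
noise floors under the stated noise model, not robustness to every
artifact of real plates.

## Reproducibility and problem sizes

All randomness flows from one integer seed through independent named
streams (truth, traces, snapshot, counts), so identical config + seed give
bitwise-identical tables and reports. The test suite exercises reduced
panels (~150 genes, ~300–750 cells) for speed and the full study scale
where the property demands it; `scripts/acceptance.py` runs the complete
study-scale pipeline plus the 100-gene recovery benchmark in a few minutes
on one CPU. Filter conservation (input = kept + removed), the Bonferroni
threshold, and every stage parameter are logged in the machine-readable
run report.

## Known limitations

* Exact reproduction of gene lists from trajectory-based DE tools is not
  attempted: their test internals and smoothing defaults differ from this
  package's explicit NB-GLM/LRT and are typically not documented.
* Onset times are grid-resolved (10 min) and noise-limited (~±15 min SD
  per gene at realistic counts); interpret per-gene onsets accordingly and
  prefer the wave-level summaries.
* The calibration clamps rather than extrapolates outside the observed
  trace range, so cells brighter than the end-of-G1 level all map to the
  range end; analyses near the 9-h boundary should treat those flags
  explicitly.
* Supplying real counts, FACS, and trace tables in the documented formats
  runs the identical pipeline; how closely the outputs match published
  values then depends on normalization scheme and smoothing choices, both
  of which are logged per run.
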