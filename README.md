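# cycledecay

Time-resolved single-cell analysis of mRNA decay at the mitosis-to-G1
(M–G1) transition.

## The problem

As human cells finish mitosis and enter G1 phase, the transcriptome is
"reset": many G2/M-specific mRNAs are actively degraded rather than simply
diluted out after transcription shuts down. Measuring *when* each
transcript starts to decline and *how fast* it decays requires absolute
cell-cycle time for every sequenced cell — something trajectory-inference
pseudotime cannot provide.

`cycledecay` implements the full analysis for experiments that combine
FUCCI reporter imaging, index-FACS sorting, and plate-based scRNA-seq
(SORT-seq/CEL-Seq2):

1. **FUCCI time calibration** — the mean FUCCI-G1 reporter trace from live
   imaging (aligned at the metaphase-to-anaphase transition, crosstalk-
   corrected with the 31% G1→G2 bleed-through factor, normalized to the
   mean early-S-phase intensity) is fit to a third-order polynomial
   `p(t)` and inverted per cell to convert FACS fluorescence into minutes
   since metaphase.
2. **QC and normalization** — cells are kept when their UMI total lies in
   [5900, 111000]; per-cell mRNA recovery is corrected with size factors;
   genes enter analysis when their mean raw count over G2/M cells is ≥ 2 in
   every 384-well plate.
3. **Differential expression** — a negative-binomial GLM likelihood-ratio
   test compares G2/M cells with G1 cells from the first 4 h, with a 2-fold
   change cutoff and a Bonferroni threshold (0.05 / #detected genes;
   e.g. 0.05/3985 = 1.2547×10⁻⁵ for a 3985-gene panel).
4. **Decay waves** — each downregulated gene's expression-vs-time profile
   is fit with a penalized smoothing spline; the time of the steepest
   decline and the first time the −1-normalized derivative reaches −0.95
   split genes into the *immediate* (mitotic exit) and *delayed* (early G1)
   decay waves.
5. **Decay kinetics** — per gene, a two-phase model

   ```
   m(t) = m0                                              t <  t_onset
   m(t) = mu/gamma + (m0 − mu/gamma)·exp(−gamma(t−t_onset))   t ≥ t_onset
   ```

   is fit by grid search over `t_onset` (0–370 min, 10-min steps) with
   bounded least squares over (m0, mu, gamma) at each onset; the onset with
   minimal SSE wins, and half-life = ln 2 / gamma.

A seeded synthetic-data generator reproduces the full study design (3
plates, 86 G2/M + 755 G1 cells over 0–540 min, ~3985-gene panel with two
planted onset waves, NB counts with per-cell capture variation, FUCCI
traces with amplitude heterogeneity and channel crosstalk) with complete
ground truth, so every stage is testable without any external data.

## Worked example

```python
from cycledecay import RunConfig, SimulationConfig, run_pipeline

config = RunConfig(simulation=SimulationConfig(rng_seed=1))
report = run_pipeline(config, out_dir="run1")

qc = report["stages"]["qc"]
print(qc["n_kept"], "cells pass QC;", qc["n_genes_detected"], "genes detected")
print(report["stages"]["de"]["n_down"], "genes downregulated")
print(report["stages"]["waves"]["group_sizes"])
print(round(report["stages"]["fit_decay"]["median_half_life"], 1),
      "min median half-life")
```

prints

```
841 cells pass QC; 3137 genes detected
187 genes downregulated
{'immediate': 108, 'delayed': 79}
57.7 min median half-life
```

Reading: of 871 sorted wells, the 30 planted low/high-UMI failures are
removed, leaving 841 cells. 187 genes are called ≥2-fold down in early G1
at the Bonferroni threshold; the spline slope analysis splits them into an
immediate wave (steepest decline at mitotic exit) and a delayed wave
(steepest decline ~80 min into G1), and the kinetic fits give a median
mRNA half-life of ~58 min in the decay phase — far shorter than typical
interphase half-lives, the signature of scheduled decay. `run1/` contains
the timed-cell table, DE table, wave calls, decay fits, calibration JSON,
ground-truth tables, and the run report with every parameter and filter
count logged.

The same stages are available as CLI subcommands over CSV/MTX/TSV files:

```bash
cycledecay simulate  --seed 1 --out-dir data/
cycledecay calibrate --traces data/traces.csv --out cal.json
cycledecay timestamp --facs data/facs.csv --calibration cal.json --out timed.csv
cycledecay qc        --counts data/ --out-dir qcd/
cycledecay de        --counts qcd/ --cells timed.csv --out de.tsv
cycledecay waves     --counts qcd/ --cells timed.csv --out waves.tsv
cycledecay fit-decay --counts qcd/ --cells timed.csv --out fits.tsv
cycledecay run-all   --seed 1 --out-dir run1/
```

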