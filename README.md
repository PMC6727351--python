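# celldeconv

Reference-free cell-type deconvolution for bulk expression and DNA
methylation data, with iterative, model-driven marker selection.

Tissue samples are mixtures of cell types, and the observed
features-by-samples matrix **Y** factorizes as **Y = WH**: **W** holds the
pure cell-type profiles and **H** the per-sample mixing proportions (each
column on the unit simplex; **W** bounded to [0, 1] for methylation beta
values). Reference-free (RF) deconvolution estimates both factors from
**Y** alone — but its accuracy hinges on selecting features that are truly
cell-type specific. Choosing features by overall variance, the common
heuristic, also drags in features with high *within*-type variability,
which actively mislead the factorization.

This package iterates between the two halves of the problem:

1. deconvolve the current feature list to get proportions **H**;
2. with **H** as the design, fit per feature the linear model
   E(Y_p) = V β_p (V = **H**ᵀ, β_p the per-cell-type means) and test each
   one-vs-rest contrast H₀: μ_pk = (1/(K−1)) Σ_{i≠k} μ_pi with a Wald t
   test (variance-floored, df = N − K);
3. keep the top 1000 features balanced across cell types and repeat.

The endpoint is the iteration with the smallest reconstruction RMSE —
observable without ground truth and inversely associated with accuracy.
The same contrast test doubles as a cell-type-specific
differential-expression screen for mixed RNA-seq samples, and a
constrained-least-squares reference-based estimator is included for when a
purified signature matrix is available.

Intended users: computational biologists estimating cell composition from
bulk microarray/RNA-seq/methylation matrices without purified references,
and methodologists benchmarking deconvolution pipelines (the simulation
module generates fully ground-truthed synthetic studies).

## Worked example

`examples/iterative_refinement.py` simulates a four-cell-type expression
study (P = 5000 features, N = 100 samples, Dirichlet-mixed subject-specific
log-normal panels) and runs the loop from the deliberately imperfect
1001–2000 variance window:

```
iter  rmse      corr-with-truth  marker-overlap
   0    127.03            0.961             250
   1    177.19            0.975             995
   2    165.95            0.982             969
   3    166.47            0.990             972
   4    163.00            0.980             966  <- chosen
   5    173.80            0.989             969
   6    182.03            0.961             974
   7    183.74            0.968             983
   8    184.60            0.971             988
```

Iteration 0 is the baseline: only 250 of its 1000 variance-selected
features are genuine cell-type markers. One refinement round already finds
995 of the 1000 planted markers, and the mean per-type correlation between
estimated and true proportions rises from 0.961 to 0.980 at the chosen
(smallest-RMSE among iterations ≥ 1) endpoint. On harder draws the gap is
larger — `examples/simulate_and_deconvolve.py` shows a dataset where
variance-selected features give a mean correlation of 0.552 while true
markers give 0.945.

Other examples: `crosscell_differential_rnaseq.py` (marker discovery in
mixed RNA-seq counts), `reference_based_estimate.py` (exact recovery with
a known signature).

## Command line

```bash
celldeconv simulate --modality expression --p 5000 --n 100 --k 4 --seed 1 --out-dir sim/
celldeconv run --input sim/mixture.tsv --k 4 --max-iter 30 --seed 1 --out-dir fit/
celldeconv evaluate --est fit/proportions.tsv --truth sim/true_proportions.tsv
```

`run` writes `proportions.tsv`, `signature.tsv`, `features.txt` and a
per-iteration `trace.tsv`; matrices are TSV with feature IDs in the first
column and sample IDs in the header (CSV accepted on read).

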