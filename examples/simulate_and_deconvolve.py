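"""Simulate a bulk expression mixture and estimate its cell composition.

Builds a synthetic four-cell-type expression dataset (log-normal pure
panels mixed by Dirichlet proportions) and deconvolves it twice: once on
the 1000 most variable features — the conventional choice — and once on
the planted cell-type-specific markers. The per-type correlations say how
well the estimated mixing fractions track the truth across samples; the
gap between the two runs is why marker selection, not raw variance, is the
thing to optimize.
"""

import numpy as np

import celldeconv as cd
from celldeconv import simulate as sim

params = sim.default_panel_params(p=2000, k=4, n_markers_per_type=100, seed=1)
data = sim.simulate_expression_dataset(params, n=50, seed=1)

for label, features in [
    ("top-1000 by variance", cd.initial_features(data.mixture, "variance_window", (1, 1000))),
    ("true planted markers", data.truth_markers),
]:
    result = cd.rf_deconvolve(data.mixture.restrict(features.feature_ids), k=4, seed=1)
    report = cd.evaluate_estimate(result.H, data.h_true)
    print(f"{label}:")
    print("  per-type correlation:", np.round(report.per_type_correlation, 3))
    print(f"  mean correlation:     {report.mean_correlation:.3f}")
    print(f"  RMSBias:              {report.rms_bias:.4f}")
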