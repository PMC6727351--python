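"""Detect cell-type-specific genes in mixed RNA-seq samples.

Simulates negative-binomial counts for mixtures of four cell types with
planted cell-type-specific differentially expressed genes, then tests each
gene's one-vs-rest contrast using the known mixing proportions as the
design. The output reports how many of the top-ranked genes are truly
differential — the precision of marker discovery from bulk data alone.
"""

import numpy as np

from celldeconv import simulate as sim
from celldeconv.diff import crosscell_differential

data, truth = sim.simulate_rnaseq_counts(
    p=4000, n=60, k=4, n_true_degs=800, lfc_sd=1.5, dispersion=0.1, seed=3
)
logged = sim.log_normalize_counts(data.mixture)
res = crosscell_differential(logged, data.h_true)

min_p = res.pvalue.min(axis=1)
order = np.argsort(min_p, kind="stable")
for top_n in (100, 400, 800):
    hits = truth["is_deg"].to_numpy()[order[:top_n]].sum()
    print(f"top {top_n:4d} genes by min p-value: {hits} true DEGs ({100*hits/top_n:.0f}%)")
print("(800 of 4000 genes are truly cell-type specific)")
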