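"""Two-end Wilcoxon rank-scoring of gene sets on a gene eigenvector.

One gene set is planted at the high end of the endogenous gene
eigenvector; 100 null sets are drawn uniformly.  The planted set should
rank first with a Bonferroni-adjusted p-value far below 0.05 while the
null sets behave like uniform noise.
"""

import numpy as np

from dualeigen import (
    SimulationSpec,
    compute_svd,
    enrich_collection,
    generate_genesets,
    generate_profile,
)

profile, truth = generate_profile(SimulationSpec(seed=7))
pooled = compute_svd(profile)
k = int(np.argmax(np.abs(pooled.u[:, :3].T @ truth.endo_u)))
u = pooled.gene_loadings(k)

collection = generate_genesets(truth, n_null_sets=100, seed=8)
results = enrich_collection(u, collection, min_size=5)

print("top 5 of 101 scored sets (both ends, Bonferroni over sets):")
print("set             size  end    p(best end)   p_adjusted")
for r in results[:5]:
    print(f"{r.name:15s} {r.size:4d}  {r.end:5s}  {min(r.p_low, r.p_high):.3g}"
          f"       {r.p_adjusted:.3g}")
print("\nThe planted set concentrates at one extreme of the sorted gene")
print("loadings; by rank duality it is equally down-enriched at the other end.")
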