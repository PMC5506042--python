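"""PWM affinity scanning and running-sum motif/loading association.

Promoters are simulated with a consensus AGGTCA site planted preferentially
among the genes at the top of the endogenous eigenvector.  The binding
strength of each promoter (transformed tail probability of its best
log-odds window) is then tested for concentration along the sorted gene
list with a mean-centered running-sum maximum and a permutation null.
"""

import numpy as np

from dualeigen import (
    PWM,
    SimulationSpec,
    base_association,
    compute_svd,
    generate_profile,
    generate_promoters,
    scan_pwm_affinity,
)

profile, truth = generate_profile(SimulationSpec(seed=7))
pooled = compute_svd(profile)
k = int(np.argmax(np.abs(pooled.u[:, :3].T @ truth.endo_u)))
u = pooled.gene_loadings(k)
if u.to_numpy() @ truth.endo_u < 0:   # orient toward the planted high end
    u = -u

planted = PWM.from_consensus("planted_AGGTCA", "AGGTCA")
null = PWM.from_consensus("null_CCGGAA", "CCGGAA")
promoters = generate_promoters(truth, planted, promoter_length=200, seed=9)
print(f"{len(promoters)} promoters; {len(truth.planted_motif_genes)} carry a planted site")

for pwm in (planted, null):
    affinity = scan_pwm_affinity(promoters, pwm)
    res = base_association(u, affinity, n_perm=999, seed=10)
    print(f"{pwm.name:15s} score={res.score:8.2f}  end={res.end:4s}  "
          f"perm p={res.p_value:.4g}")
print("\nThe planted motif's affinity concentrates at the head of the sorted")
print("list (small p); the unrelated motif is indistinguishable from a shuffle.")
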