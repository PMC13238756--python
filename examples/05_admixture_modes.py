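"""Post-process replicate admixture runs: mode clustering and Evanno delta-K.

Replicate Q matrices from an EM admixture program are label-switched and can
converge to different solutions; this groups them into modes at similarity
>= 0.85, averages the major mode, and scores K by the Evanno statistic.
"""

import numpy as np
import pandas as pd

from cudelim.containers import AdmixtureRun
from cudelim.structure import cluster_runs, evanno_delta_k

rng = np.random.default_rng(5)
n_ind, K = 60, 3
base = rng.dirichlet([4, 2, 1], size=n_ind)
idx = [f"ind{j:02d}" for j in range(n_ind)]

runs = []
for r in range(8):
    q = np.abs(base + rng.normal(0, 0.01, base.shape))
    q /= q.sum(axis=1, keepdims=True)
    q = q[:, rng.permutation(K)]  # label switching between replicates
    runs.append(AdmixtureRun(K, pd.DataFrame(q, index=idx),
                             -1000 - rng.random(), f"run{r}"))
# two runs stuck in a different local optimum
for r in range(8, 10):
    q = rng.dirichlet([1, 1, 1], size=n_ind)
    runs.append(AdmixtureRun(K, pd.DataFrame(q, index=idx),
                             -1100 - rng.random(), f"run{r}"))

res = cluster_runs(runs, sim_threshold=0.85)
print(f"{len(res.modes)} modes; major mode holds {len(res.modes[0])}/10 runs")
print("major-mode averaged ancestry of the first 3 individuals:")
print(res.major_q.head(3).round(3).to_string())

lik = {k: list(-2000 + 120 * min(k, 3) + rng.normal(0, 3, 5)) for k in range(1, 7)}
dk = evanno_delta_k(lik)
print("\nEvanno delta-K by K (peaks mark supported cluster counts):")
print(dk["delta_k"].round(2).to_string())
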