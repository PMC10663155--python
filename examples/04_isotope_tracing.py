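"""Stable-isotope tracing: match m+0..m+5 isotopologues, strip natural
13C abundance (binomial, P = 0.01109), and cluster labeled metabolites by
consensus spatial correlation over mixed-clone pixels with a permutation
null.
"""

import warnings

import numpy as np

from ioncoloc.isotrace import MetaboliteSpec, trace_colocalization
from ioncoloc.peakflow import preprocess_runs
from ioncoloc.synthio import DEFAULT_METABOLITES, SynthConfig, generate_biclonal_runs

warnings.filterwarnings("ignore")

runs, truth = generate_biclonal_runs(SynthConfig(grid_w=32, grid_h=32, seed=7))
ft = preprocess_runs(runs)

specs = [MetaboliteSpec(m.name, m.base_mz, m.n_carbons) for m in DEFAULT_METABOLITES]
label_k = {m.name: m.label_k for m in DEFAULT_METABOLITES}
res = trace_colocalization(ft, specs, label_k=label_k, n_perm=1000, seed=7)

print("consensus correlation (minimum across runs, mix pixels only):")
for i, a in enumerate(res.names):
    row = "  ".join(f"{res.consensus[i, j]:+.2f}" for j in range(len(res.names)))
    print(f"  {a:15s} {row}")
print("permutation q-values (BH over pairs):")
iu = np.triu_indices(len(res.names), 1)
for i, j in zip(*iu):
    print(f"  {res.names[i]} ~ {res.names[j]}: q = {res.q[i, j]:.4f}")
print(f"two-cluster cut: { {n: int(c) for n, c in zip(res.names, res.cluster_labels)} }")
# Krebs-cycle proxies (labeled in MYC-high zones) should cluster apart from
# the lactagenic proxies (labeled in MYC-low zones), with significant
# positive within-group and negative between-group consensus.
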