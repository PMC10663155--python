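"""Conditional-probability coexpression tables and the Fisher-scaled
pathway enrichment score on a small synthetic significance table.
"""

import numpy as np
import pandas as pd

from ioncoloc.clonstat import conditional_coexpression, cov_filter, pathway_enrichment

rng = np.random.default_rng(5)

# conditional probabilities of low/mid/high intensity given MYC genotype
genotype = np.repeat(["high", "low"], 300)
intensity = np.where(genotype == "high",
                     rng.lognormal(1.2, 0.4, 600), rng.lognormal(0.8, 0.4, 600))
tab = conditional_coexpression(intensity, genotype)["f0"]
print("P(level | genotype):")
print(tab.probs.round(3).to_string())
# Columns sum to 1; mass shifting to 'high' under MYC-high genotype means
# the ion coexpresses with the MYC-high clone.

# CoV filter: keep features stable (< 30% CoV) in at least one class
stable = rng.normal(100, 5, (10, 6))        # ~5% CoV everywhere
erratic = rng.lognormal(2, 1.0, (10, 6))    # ~130% CoV everywhere
vals = pd.DataFrame(np.vstack([stable, erratic]),
                    columns=[f"s{i}" for i in range(6)])
kept = cov_filter(vals, ["high"] * 3 + ["low"] * 3)
print(f"\nCoV filter kept {len(kept)}/20 features (the 10 stable ones)")

# pathway enrichment: 15 of a 20-feature pathway significant toward 'high'
n = 400
sig = pd.DataFrame({
    "feature": [f"f{i}" for i in range(n)],
    "p": np.where(np.arange(n) < 40, 0.01, 0.5),
    "direction": np.where(np.arange(n) % 2 == 0, "high", "low"),
})
memb = pd.DataFrame({"feature": [f"f{2 * i}" for i in range(15)],
                     "pathway": ["coa_biosynthesis"] * 15})
res = pathway_enrichment(sig, memb)
print(res.round(3).to_string(index=False))
# score = (observed/expected hits) x (-log10 Fisher p), per direction: a
# pathway enriched among MYC-high-elevated ions scores high in 'high'.
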