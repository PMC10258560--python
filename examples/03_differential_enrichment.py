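"""Gene-level differential enrichment between a start and an end point.

Simulates a 200-gene count table with negative-binomial noise in which three
genes are 20-fold enriched after selection, then runs the combined-count
filter (>= 128), the conditional NB exact test with moment-estimated common
dispersion, and Benjamini-Hochberg adjustment.
"""

import numpy as np
import pandas as pd

from tntrace.enrichment import differential_enrichment

rng = np.random.default_rng(11)
n_genes, depth, phi = 200, 40_000, 0.05
mu = np.full(n_genes, depth / n_genes)
mu_end = mu.copy()
mu_end[[3, 50, 120]] *= 20  # truly enriched genes
r = 1 / phi
table = pd.DataFrame(
    {
        "start": rng.negative_binomial(r, r / (r + mu)),
        "end": rng.negative_binomial(r, r / (r + mu_end)),
    },
    index=[f"gene{i:03d}" for i in range(n_genes)],
)
table.attrs["library_sizes"] = {"start": int(table["start"].sum()),
                                "end": int(table["end"].sum())}

result = differential_enrichment(table)
print(result.sort_values("q").head(6).to_string(
    float_format=lambda x: f"{x:.3g}"))
print(f"\ndispersion estimate: {result.attrs['dispersion']:.3f} "
      f"(method of moments, floored at 0.01)")
print("The three enriched genes (gene003, gene050, gene120) should occupy the")
print("smallest q values with log2FC near log2(20) = 4.3; all other genes")
print("should sit near log2FC 0 with q ~ 1.")
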