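"""Pathway-level carrier odds ratios on the packaged reference layouts.

For each implicated pathway, individuals carrying at least one qualifying
variant in any member gene form the "exposed" arm of a carrier-level 2×2
table.  The packaged layouts reproduce the published per-pathway carrier
counts (119 cases vs 1337 controls).
"""

import numpy as np

from npcpipe.cohort_io import CarrierMatrix
from npcpipe.datasets import PATHWAY_TABLES, pathway_gene_sets
from npcpipe.pathway import enrichment_fisher_right, pathway_carrier_test

for name in ["GM-CSF Signalling", "Caveolar-mediated Endocytosis Signalling"]:
    t = PATHWAY_TABLES[name]
    n = t.case_n + t.control_n
    dosage = np.zeros((n, 1), dtype=np.int8)
    dosage[: t.a, 0] = 1
    dosage[t.case_n : t.case_n + t.c, 0] = 1
    matrix = CarrierMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_keys=[("1", 100, "A", "G")],
        dosage=dosage,
        phenotype=["case"] * t.case_n + ["control"] * t.control_n,
    )
    pw = next(s for s in pathway_gene_sets() if s.name == name)
    qualifying = {g: [("1", 100, "A", "G")] for g in list(pw.genes)[:1]}
    table, est, lo, hi, p = pathway_carrier_test(pw, qualifying, matrix)
    print(f"{name}:")
    print(f"  carriers {table.a}/{table.case_n} cases vs {table.c}/{table.control_n} controls")
    print(f"  carrier OR {est:.1f} ({lo:.1f}-{hi:.1f}), p = {p:.3g}")

print("\nhypergeometric enrichment needs an explicit gene universe, e.g.")
p = enrichment_fisher_right(k=6, K=70, n=559, N=20000)
print(f"  6 of 70 pathway genes among 559 significant of 20000: p = {p:.3g}")
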