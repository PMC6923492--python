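"""Explain a gene's combined essentiality with its molecular features.

Regresses one essential gene's fitted CES across cell lines on its four
molecular features.  A negative weight means the feature pushes the
gene toward stronger essentiality (lower CES).
"""

import cescore as ces

data = ces.generate(ces.SimulationConfig(n_genes=2000, n_cell_lines=40,
                                         seed=20191112))
crispr = ces.zscore_normalize(data.crispr)
shrna = ces.zscore_normalize(data.shrna)
features = ces.zscore_normalize(data.features)
fit = ces.fit_ces(crispr, shrna, features)

for gene in data.truth.genes_with_label("essential")[:3]:
    res = ces.biomarker_regression(fit, features, gene)
    print(f"{gene} (n = {res.n_cell_lines} cell lines):")
    for eff in res.effects:
        flag = "*" if eff.p_value < 0.05 else " "
        print(f"  {eff.feature:10s} weight {eff.estimate:+.3f} "
              f"(se {eff.std_error:.3f}, p = {eff.p_value:.2g}){flag}")
# Copy number and the two expression platforms should carry negative,
# often significant weights: amplified / highly expressed genes are
# predicted to be more essential.  Mutation is a deliberately weak
# signal and is usually non-significant for any single gene.
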