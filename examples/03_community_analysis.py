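"""Alpha diversity, ordination and PERMANOVA on a synthetic community.

Generates a bacterial Dirichlet-multinomial community over a simulated
trial (treatment-specific phylum profiles), then runs the standard
beta-diversity chain: Bray-Curtis distances, principal coordinates, and
a seeded PERMANOVA of the treatment effect.
"""

import pandas as pd

from milletsoil.community import (alpha_diversity_table, bray_curtis, pcoa,
                                  permanova)
from milletsoil.synth import (CommunityConfig, TrialConfig,
                              generate_abundance_dataset,
                              generate_soil_dataset)

cfg = TrialConfig(replicates=5, years=(2022,))
soil = generate_soil_dataset(cfg, seed=4)
cc = CommunityConfig(kingdom="bacteria")
table = generate_abundance_dataset(cc, soil, seed=4)

counts = (table.matrix * cc.depth).round()
alpha = alpha_diversity_table(counts)
print("alpha diversity (first 4 samples):")
print(alpha.head(4).round(2).to_string())

d = bray_curtis(table.matrix.T.to_numpy())
ordn = pcoa(d, k=2)
print(f"\nPCoA axis 1 explains {ordn.proportion_explained[0]:.1%}, "
      f"axis 2 {ordn.proportion_explained[1]:.1%} "
      f"(negative eigenvalues present: {ordn.has_negative_eigenvalues})")

labels = [s.split("_")[0] for s in table.samples]
res = permanova(d, labels, n_perm=999, seed=4)
print(f"PERMANOVA: pseudo-F = {res.pseudo_f:.2f}, p = {res.p_value:.3f}")
print("\nA small p confirms the generator's phylum-level treatment shifts")
print("separate the communities in Bray-Curtis space.")
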