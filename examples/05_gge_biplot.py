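"""GGE biplot of a diallel entry x tester table.

Each genotype is both an entry (row) and a tester (column); the table is
tester-centered and decomposed by SVD.  Entry projections on the average
tester coordinate (ATC) abscissa approximate GCA; the polygon view names,
for each tester, the entry predicted to be its best mate.
"""

import numpy as np

from diallelkit import (SimulationSpec, build_entry_tester_matrix,
                        center_by_tester, default_design, entry_means,
                        griffing2_effects, polygon_sectors, simulate_diallel,
                        svd_biplot)

design = default_design(method="method2", n_envs=1)
spec = SimulationSpec(design=design, sigma2_g=2.0, sigma2_s=0.4,
                      sigma2_e=0.5, delta_self=-1.5, seed=12)
records, _ = simulate_diallel(spec)

x = entry_means(records, "yield", "E1", design)
model = svd_biplot(center_by_tester(build_entry_tester_matrix(x)))
print(f"PC1 + PC2 explain {100 * model.explained[:2].sum():.1f}% "
      "of the tester-centered variation")

g = griffing2_effects(x).g
rho = np.corrcoef(model.atc_abscissa, g)[0, 1]
print(f"correlation of ATC abscissa with Griffing g: {rho:.3f} "
      "(biplot GCA ranking agrees with Griffing's)")

poly = polygon_sectors(model)
print("\npredicted best mate per tester (polygon sector winner):")
for tester, winner in poly.sector_of_tester.items():
    own = " <- selfing wins (low heterosis)" if winner == tester else ""
    print(f"  {tester}: {winner}{own}")
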