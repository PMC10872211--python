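"""Climatic niche space: PCA over distribution cells, population
projection, niche and geographic distances.
"""

import numpy as np

from _common import load, save, write_table
from wildg import niche as ni

study = load("study")
space = ni.fit_niche_pca(study.grid)
proj = ni.project_populations(space, study.sites, study.grid)
niche_d = ni.niche_distances(proj)
geo_d = ni.geographic_distances(study.sites)
save("niche", {"space": space, "projection": proj, "niche_d": niche_d, "geo_d": geo_d})

ef = space.explained_fraction
print(f"niche PCA: PC1 {ef[0]*100:.0f}%, PC2 {ef[1]*100:.0f}% of climate variance")
print("population positions (distance to niche center):")
for _, r in proj.table.iterrows():
    print(f"  {r.population}: PC1 {r.pc1:+.2f}, PC2 {r.pc2:+.2f}, center distance {r.center_distance:.2f}")
iu = np.triu_indices(len(niche_d), k=1)
r = np.corrcoef(niche_d.to_numpy()[iu], geo_d.to_numpy()[iu])[0, 1]
print(f"niche vs geographic distance correlation: r = {r:.2f} "
      f"(geographic span {geo_d.to_numpy()[iu].min():.0f}-{geo_d.to_numpy()[iu].max():.0f} km)")
write_table(proj.table, "population_projections")
write_table(niche_d.reset_index(), "niche_distances")
write_table(geo_d.reset_index(), "geographic_distances")
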