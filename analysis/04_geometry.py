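"""G-matrix geometry: g_max orientation, eccentricity, and volume per
population, plus pairwise orientation divergence tests.
"""

import numpy as np
import pandas as pd

from _common import SEED, load, save, write_table
from wildg.geometry import gmax_divergence_test, gmax_summary

tensor = load("tensor")
out = {}
rows = []
div_rows = []
for group, res in tensor.items():
    gset = res["gset"]
    gm = {p: gmax_summary(gset.draws[p], gset.traits) for p in gset.populations}
    out[group] = gm
    print(group)
    for p, s in gm.items():
        summ = s.summary.set_index("statistic")
        print(
            f"  {p}: g_max = {np.round(s.gmax, 2)}, eccentricity "
            f"{summ.loc['eccentricity', 'mode']:.2f}, volume {summ.loc['volume', 'mode']:.2f}"
            + (" [degenerate]" if s.degenerate else "")
        )
        for stat in ("leading_eigenvalue", "eccentricity", "volume"):
            r = summ.loc[stat].to_dict()
            rows.append({"group": group, "population": p, "statistic": stat, **r})
    pops = gset.populations
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            rep = gmax_divergence_test(
                gm[pops[i]].gmax_draws, gm[pops[j]].gmax_draws, seed=SEED + i * 10 + j
            )
            div_rows.append(
                {
                    "group": group,
                    "pop_a": pops[i],
                    "pop_b": pops[j],
                    "median_between_angle": rep["median_between"],
                    "supported": rep["support"],
                }
            )
save("geometry", out)
write_table(pd.DataFrame(rows), "gmax_summaries")
div = pd.DataFrame(div_rows)
write_table(div, "gmax_divergence")
for group in tensor:
    sub = div[div.group == group]
    print(f"{group}: orientation divergence supported for {sub.supported.sum()}/{len(sub)} pairs")
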