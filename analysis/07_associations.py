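"""Relate G-matrix divergence to climatic divergence.

Life history: tensor distances and g_max angles against niche distances
(Mantel + randomized slope regressions), the data slope against the null
slope, standardized laying-date Va and G volume against the distance to
the niche center, and a leave-two-out robustness rerun.  Morphology runs
the same battery without a planted gradient as the negative contrast.
"""

import numpy as np
import pandas as pd

from _common import SEED, load, write_table
from wildg import association as assoc, nullmodel as nm, tensor as tn
from wildg.geometry import _pairwise_angles

tensor = load("tensor")
niche = load("niche")
null = load("null")
niche_d = niche["niche_d"]
center = niche["projection"].table.set_index("population")["center_distance"]

rows = []
for group, res in tensor.items():
    gset = res["gset"]
    bundle_assoc = assoc.associate(gset, niche_d, seed=SEED, n_perm=999)
    a = bundle_assoc
    print(f"{group}:")
    print(
        f"  tensor distance ~ niche distance: Mantel r = {a.mantel_tensor.r:.2f} "
        f"(p = {a.mantel_tensor.p_value:.3f}); slope {a.slope_tensor.median:.3f} "
        f"[{a.slope_tensor.ci95[0]:.3f}:{a.slope_tensor.ci95[1]:.3f}]"
        f"{' *' if a.slope_tensor.significant else ''}"
    )
    print(
        f"  g_max angle ~ niche distance: Mantel r = {a.mantel_angle.r:.2f}; "
        f"slope {a.slope_angle.median:.2f} "
        f"[{a.slope_angle.ci95[0]:.2f}:{a.slope_angle.ci95[1]:.2f}]"
        f"{' *' if a.slope_angle.significant else ''}"
    )
    gm = load("geometry")[group]
    volume = {p: gm[p].volume for p in gset.populations}
    sl_vol = assoc.posterior_vs_gradient(volume, center)
    pc1 = niche["projection"].table.set_index("population")["pc1"]
    va1 = {p: gset.draws[p][:, 0, 0] for p in gset.populations}
    sl_va = assoc.posterior_vs_gradient(va1, pc1)
    first = gset.traits[0]
    print(
        f"  volume ~ center distance: slope {sl_vol.median:.2f} "
        f"[{sl_vol.ci95[0]:.2f}:{sl_vol.ci95[1]:.2f}]{' *' if sl_vol.significant else ''}"
    )
    print(
        f"  {first} Va ~ niche PC1 (temperature axis): slope {sl_va.median:.2f} "
        f"[{sl_va.ci95[0]:.2f}:{sl_va.ci95[1]:.2f}]{' *' if sl_va.significant else ''}"
    )
    row = {
        "group": group,
        "mantel_r": a.mantel_tensor.r,
        "mantel_p": a.mantel_tensor.p_value,
        "slope_median": a.slope_tensor.median,
        "slope_lo": a.slope_tensor.ci95[0],
        "slope_hi": a.slope_tensor.ci95[1],
        "angle_slope_median": a.slope_angle.median,
        "angle_slope_lo": a.slope_angle.ci95[0],
        "angle_slope_hi": a.slope_angle.ci95[1],
        "volume_center_slope": sl_vol.median,
        "va_first_trait_pc1_slope": sl_va.median,
    }

    if group == "life_history":
        ndraws = nm.null_distance_draws(null["null_sets"])
        slope_null = assoc.randomized_distance_regression(ndraws, niche_d, seed=SEED + 3)
        p_cmp = assoc.slope_comparison(a.slope_tensor, slope_null, seed=SEED + 4)
        print(
            f"  null slope {slope_null.median:.3f} "
            f"[{slope_null.ci95[0]:.3f}:{slope_null.ci95[1]:.3f}]; "
            f"data > null at p = {p_cmp:.3f}"
        )
        row.update(null_slope_median=slope_null.median, p_slope_vs_null=p_cmp)

        # robustness: drop the two gradient-extreme populations
        extremes = center.sort_values().index[[0]].tolist() + [center.sort_values().index[-1]]
        reduced = assoc.leave_out_rerun(gset, niche_d, drop=extremes, seed=SEED, n_perm=999)
        print(
            f"  without {extremes}: slope {reduced.slope_tensor.median:.3f} "
            f"[{reduced.slope_tensor.ci95[0]:.3f}:{reduced.slope_tensor.ci95[1]:.3f}]"
        )
        row.update(
            dropped=";".join(extremes),
            slope_reduced_median=reduced.slope_tensor.median,
        )
    rows.append(row)

write_table(pd.DataFrame(rows), "associations")
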