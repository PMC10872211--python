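"""Standardize the G posteriors to the interpopulation Va-bar scale and
run the genetic covariance tensor comparison per trait group.

Prints the variance fraction each eigentensor captures and the trait
combinations driving the leading eigentensors.
"""

import numpy as np
import pandas as pd

from _common import SEED, load, save, write_table
from wildg import standardize as std, tensor as tn

bundles = load("fit_bundles")
out = {}
coord_rows = []
for group, bundle in bundles.items():
    vb = std.estimate_vabar(bundle["fits"], ndraw=1000, seed=SEED)
    gset = std.standardize_g(bundle["fits"], vb)
    decomp = tn.build_tensor(gset)
    coords = tn.coordinates(gset, decomp, n_axes=2)
    out[group] = {"vabar": vb, "gset": gset, "decomp": decomp, "coords": coords}
    print(f"{group}: Va-bar = {np.round(vb.values, 3)}")
    frac = decomp.fraction
    print(
        f"  eigentensor variance fractions: E1 {frac[0]*100:.0f}%"
        + (f", E2 {frac[1]*100:.0f}%" if len(frac) > 1 else "")
        + (f" (E1+E2 {100*(frac[0]+frac[1]):.0f}%)" if len(frac) > 1 else "")
    )
    lead = tn.eigentensor_traits(decomp, 0).iloc[0]
    loadings = ", ".join(
        f"{t} {lead[f'loading_{t}']:+.2f}" for t in decomp.traits
    )
    print(f"  E1 leading trait eigenvector ({lead['share']*100:.0f}% of E1): {loadings}")
    ci = coords.intervals.copy()
    ci.insert(0, "group", group)
    coord_rows.append(ci)

save("tensor", out)
write_table(pd.concat(coord_rows, ignore_index=True), "tensor_coordinates")
frac_rows = [
    {"group": g, "eigentensor": k + 1, "fraction": f}
    for g, res in out.items()
    for k, f in enumerate(res["decomp"].fraction)
]
write_table(pd.DataFrame(frac_rows), "tensor_fractions")
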