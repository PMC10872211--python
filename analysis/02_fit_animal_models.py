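"""Fit the Bayesian multivariate animal model per population and trait
group; check convergence; store the posteriors.

Morphology and life history get separate models (different fixed and
random structures); life-history tables pass the data-preparation
filters (first clutch per female-year, zero-truncated fledging success)
before fitting.
"""

import time

import pandas as pd

from _common import FIT_SETTINGS, RESULTS, load, save
from wildg.animal_model import convergence_diagnostics
from wildg.workflow import fit_group

study = load("study")
bundles = {}
rows = []
for group in study.config.groups:
    t0 = time.time()
    bundles[group] = fit_group(study, group, FIT_SETTINGS)
    print(f"{group}: fitted {len(bundles[group]['fits'])} populations in {time.time()-t0:.0f}s")
    fits_dir = RESULTS / "fits"
    fits_dir.mkdir(parents=True, exist_ok=True)
    for pop, post in bundles[group]["fits"].items():
        post.save(fits_dir / f"{group}_{pop}.h5")
        rep = convergence_diagnostics(post)
        rows.append(
            {
                "group": group,
                "population": pop,
                "max_lag1_autocorr": rep["lag1_autocorr"].abs().max(),
                "min_ess": rep["ess"].min(),
                "passed": rep.attrs["passed"],
            }
        )
        gmean = post.G.mean(0)
        print(
            f"  {pop}: posterior-mean Va = "
            + ", ".join(f"{post.traits[t]} {gmean[t, t]:.3f}" for t in range(len(post.traits)))
        )
save("fit_bundles", bundles)
diag = pd.DataFrame(rows)
print(diag.to_string(index=False))
print(
    "note: with 100 retained draws the lag-1 autocorrelation estimate itself "
    "has sampling noise ~0.1, so the strict <0.1 pass rule is only attainable "
    "with full-scale chains (1,000 retained draws)."
)
from _common import write_table

write_table(diag, "convergence_diagnostics")
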