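"""Shared configuration and artifact store for the numbered analysis
scripts.

Every script reads/writes pickled stage artifacts under results/cache so
the pipeline can be run stage by stage; result tables land in results/ as
CSV.  The study configuration below is the single source of truth for the
demonstration analysis: five populations on a synthetic European
temperature gradient, a climate-aligned life-history G gradient planted
(delta = 3), and a climate-free morphology branch as the contrast.
"""

import pickle
from pathlib import Path

from wildg.animal_model import MCMCSettings
from wildg.simulate import StudyConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
CACHE = RESULTS / "cache"
SEED = 20240915

STUDY = StudyConfig(
    n_populations=5,
    n_founders=250,
    n_years=12,
    delta=3.0,
    delta_morph=0.0,
    groups=("morphology", "life_history"),
    seed=SEED,
)

FIT_SETTINGS = MCMCSettings(burnin=2000, iterations=10_000, thin=100, seed=SEED)
NULL_REPLICATES = 20
NULL_SETTINGS = MCMCSettings(burnin=300, iterations=1000, thin=10, seed=SEED)


def save(name, obj):
    CACHE.mkdir(parents=True, exist_ok=True)
    with open(CACHE / f"{name}.pkl", "wb") as fh:
        pickle.dump(obj, fh)


def load(name):
    path = CACHE / f"{name}.pkl"
    if not path.exists():
        raise SystemExit(
            f"missing artifact {path.name}; run the earlier analysis scripts first"
        )
    with open(path, "rb") as fh:
        return pickle.load(fh)


def write_table(df, name):
    RESULTS.mkdir(parents=True, exist_ok=True)
    out = RESULTS / f"{name}.csv"
    df.to_csv(out, index=False)
    print(f"  wrote {out.relative_to(ROOT)}")
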