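"""Pipeline orchestration: data filters, per-stage wiring, seeding, report.

The pipeline has two independent branches — morphology and life history —
fitted and compared separately, mirroring how field studies analyse the
two trait classes.  Stages: simulate (or load) -> trait filters -> per-
population animal-model fits -> Va-bar standardization -> tensor +
geometry -> null model -> niche -> associations -> report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import geometry as geom_mod
from . import niche as niche_mod
from . import nullmodel as null_mod
from . import standardize as std_mod
from . import tensor as tensor_mod
from .animal_model import MCMCSettings, ModelSpec, build_design, fit_animal_model
from .pedigree import ainverse, inbreeding
from .simulate import StudyConfig, simulate_study

logger = logging.getLogger(__name__)


def apply_trait_filters(raw: pd.DataFrame) -> pd.DataFrame:
    """Life-history data preparation: keep only the earliest clutch per
    female-year, drop zero fledging-success records (zero truncation), and
    encode laying date as day of year with day 1 = Jan 1."""
    df = raw.copy()
    for key in ("id", "year"):
        if key not in df.columns:
            raise ValueError(f"life-history table lacks required column {key!r}")
    if "laying_date" in df.columns and not pd.api.types.is_numeric_dtype(
        df["laying_date"]
    ):
        parsed = pd.to_datetime(df["laying_date"], errors="raise")
        df["laying_date"] = parsed.dt.dayofyear.astype(float)
    sort_key = "laying_date" if "laying_date" in df.columns else "clutch_order"
    if sort_key in df.columns:
        df = (
            df.sort_values(sort_key, kind="stable")
            .groupby(["id", "year"], as_index=False, sort=False)
            .first()
        )
    if "fledging_success" in df.columns:
        df = df[df["fledging_success"] != 0]
    return df.reset_index(drop=True)


def default_model_spec(group: str, traits: list) -> ModelSpec:
    if group == "morphology":
        return ModelSpec(
            traits=traits,
            age_mode="quadratic",
            use_sex=True,
            use_sex_age=True,
            date_mode="cubic",
            use_pe=True,
            use_year=True,
            use_observer=True,
        )
    return ModelSpec(
        traits=traits,
        age_mode="quadratic",
        use_pe=True,
        use_year=True,
        use_observer=False,
    )


@dataclass
class PipelineConfig:
    """One document describing a full run."""

    simulate: StudyConfig = field(default_factory=StudyConfig)
    mcmc_profile: str = "desk"
    null_replicates: int = 50
    null_subsample: int = 100
    run_null: bool = True
    n_perm: int = 999
    vabar_ndraw: int = 1000
    seed: int = 0
    groups: tuple = ("morphology", "life_history")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulate", {})
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown pipeline config key(s): {sorted(bad)}")
        cfg = cls(**doc)
        if sim:
            sim_known = set(StudyConfig.__dataclass_fields__)
            bad = set(sim) - sim_known
            if bad:
                raise ValueError(f"unknown simulate config key(s): {sorted(bad)}")
            cfg.simulate = StudyConfig(**sim)
        cfg.groups = tuple(cfg.groups)
        cfg.simulate.groups = cfg.groups
        return cfg

    def config_hash(self) -> str:
        doc = asdict(self)
        doc["simulate"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.simulate).items()
            if not isinstance(v, dict)
        }
        for g in ("morphology", "life_history"):
            doc["simulate"].pop(g, None)
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def fit_group(
    study,
    group: str,
    settings_base: MCMCSettings,
    spec: ModelSpec | None = None,
    apply_filters: bool = True,
) -> dict:
    """Fit the animal model for one trait group in every population.

    Returns a dict with fits, designs, ainverses, inbreedings, pedigrees.
    """
    cfg = study.config
    arch = cfg.architecture(group)
    spec = spec or default_model_spec(group, list(arch.traits))
    fits, designs, ainvs, Fs = {}, {}, {}, {}
    for j, pop in enumerate(study.pedigrees):
        ped = study.pedigrees[pop]
        phen = study.phenotypes[(pop, group)]
        if group == "life_history" and apply_filters:
            phen = apply_trait_filters(phen)
        F = inbreeding(ped)
        Ai = ainverse(ped, F)
        design = build_design(phen, spec)
        settings = MCMCSettings(
            burnin=settings_base.burnin,
            iterations=settings_base.iterations,
            thin=settings_base.thin,
            seed=settings_base.seed + 1000 * j + sum(ord(c) for c in group),
        )
        t0 = time.time()
        fits[pop] = fit_animal_model(design, Ai, spec, settings, ped.ids)
        logger.info("fit %s/%s in %.1fs", pop, group, time.time() - t0)
        designs[pop] = design
        ainvs[pop] = Ai
        Fs[pop] = F
    return {
        "fits": fits,
        "designs": designs,
        "ainverses": ainvs,
        "inbreedings": Fs,
        "pedigrees": dict(study.pedigrees),
        "spec": spec,
    }


def analyse_group(
    bundle: dict,
    niche_d: pd.DataFrame,
    center_dist: pd.Series,
    seed: int,
    vabar_ndraw: int = 1000,
    n_perm: int = 999,
) -> dict:
    """Standardize -> tensor -> geometry -> associations for one group."""
    fits = bundle["fits"]
    vabar = std_mod.estimate_vabar(fits, ndraw=vabar_ndraw, seed=seed)
    gset = std_mod.standardize_g(fits, vabar)
    decomp = tensor_mod.build_tensor(gset)
    coords = tensor_mod.coordinates(gset, decomp, n_axes=min(2, len(decomp.alphas)))
    assoc = assoc_mod.associate(gset, niche_d, seed=seed, n_perm=n_perm)
    gm = {p: geom_mod.gmax_summary(gset.draws[p], gset.traits) for p in fits}
    volume = {p: gm[p].volume for p in fits}
    slope_volume = assoc_mod.posterior_vs_gradient(volume, center_dist)
    va_first = {p: gset.draws[p][:, 0, 0] for p in fits}
    slope_va_first = assoc_mod.posterior_vs_gradient(va_first, center_dist)
    return {
        "vabar": vabar,
        "gset": gset,
        "decomp": decomp,
        "coords": coords,
        "assoc": assoc,
        "gmax": gm,
        "slope_volume": slope_volume,
        "slope_va_first_trait": slope_va_first,
    }


def run_pipeline(cfg: PipelineConfig, outdir=None) -> dict:
    """Execute the full pipeline from a config; returns a report dict of
    tables and fitted objects, optionally persisting tables as CSV."""
    rng_master = np.random.SeedSequence(cfg.seed)
    study = simulate_study(cfg.simulate)
    space = niche_mod.fit_niche_pca(study.grid)
    proj = niche_mod.project_populations(space, study.sites, study.grid)
    niche_d = niche_mod.niche_distances(proj)
    geo_d = niche_mod.geographic_distances(study.sites)
    center = proj.table.set_index("population")["center_distance"]

    settings = MCMCSettings.profile(cfg.mcmc_profile, seed=cfg.seed)
    report = {
        "config": cfg,
        "niche": {
            "space": space,
            "projection": proj,
            "distances": niche_d,
            "geographic": geo_d,
        },
        "groups": {},
    }
    for gi, group in enumerate(cfg.groups):
        bundle = fit_group(study, group, settings)
        analysis = analyse_group(
            bundle,
            niche_d,
            center,
            seed=cfg.seed + 17 * (gi + 1),
            vabar_ndraw=cfg.vabar_ndraw,
            n_perm=cfg.n_perm,
        )
        result = {"bundle": bundle, "analysis": analysis}
        if cfg.run_null:
            ncfg = null_mod.NullConfig(
                n_replicates=cfg.null_replicates,
                posterior_subsample=cfg.null_subsample,
                mcmc=settings,
                seed=cfg.seed + 31 * (gi + 1),
            )
            coll = null_mod.run_null(
                bundle["fits"],
                bundle["pedigrees"],
                bundle["designs"],
                bundle["ainverses"],
                bundle["inbreedings"],
                bundle["spec"],
                ncfg,
            )
            null_sets = null_mod.null_standardized_gsets(coll)
            null_draws = null_mod.null_distance_draws(null_sets)
            slope_null = assoc_mod.randomized_distance_regression(
                null_draws, niche_d, seed=cfg.seed + 77
            )
            p_slope = assoc_mod.slope_comparison(
                analysis["assoc"].slope_tensor, slope_null, seed=cfg.seed + 78
            )
            pvals = (
                tensor_mod.tensor_null_pvalues(analysis["decomp"], null_sets)
                if len(null_sets) >= 20
                else None
            )
            result["null"] = {
                "collection": coll,
                "slope_null": slope_null,
                "p_slope_vs_null": p_slope,
                "tensor_pvalues": pvals,
            }
        report["groups"][group] = result

    report["tables"] = summary_tables(report)
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tbl in report["tables"].items():
            tbl.to_csv(out / f"{name}.csv", index=False)
        save_figures(report, out)
    return report


def save_figures(report: dict, outdir) -> list:
    """Figure analogues of the headline displays: eigentensor coordinates
    per population with credible intervals, and tensor distance against
    niche distance with the randomized-regression slope band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    written = []
    niche_d = report["niche"]["distances"]
    for group, res in report["groups"].items():
        an = res["analysis"]
        coords = an["coords"]
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        ax = axes[0]
        for j, pop in enumerate(coords.populations):
            sub = coords.intervals.query("population == @pop and eigentensor == 1")
            w95 = sub[sub.level == 0.95]
            ax.errorbar(
                [j],
                w95["mode"],
                yerr=[
                    w95["mode"].to_numpy() - w95["lo"].to_numpy(),
                    w95["hi"].to_numpy() - w95["mode"].to_numpy(),
                ],
                fmt="o",
                capsize=3,
            )
        ax.set_xticks(range(len(coords.populations)), coords.populations, rotation=45)
        ax.set_ylabel("coordinate on eigentensor 1")
        ax.set_title(f"{group}: tensor coordinates")

        ax = axes[1]
        dset_mode = None
        pops = an["gset"].populations
        from .tensor import tensor_distances

        dset = tensor_distances(coords, k=min(2, coords.n_axes))
        x, y = [], []
        m = len(pops)
        D = niche_d.loc[pops, pops].to_numpy()
        for i in range(m):
            for j in range(i + 1, m):
                x.append(D[i, j])
                y.append(dset.mode[i, j])
        ax.scatter(x, y)
        sl = an["assoc"].slope_tensor
        xs = np.linspace(min(x), max(x), 20)
        inter = np.mean(y) - sl.median * np.mean(x)
        ax.plot(xs, inter + sl.median * xs)
        ax.set_xlabel("niche distance")
        ax.set_ylabel("tensor distance (posterior mode)")
        ax.set_title(
            f"slope {sl.median:.2f} [{sl.ci95[0]:.2f}:{sl.ci95[1]:.2f}]"
        )
        fig.tight_layout()
        path = outdir / f"figure_{group}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def summary_tables(report: dict) -> dict:
    """Tidy CSV-ready tables from a pipeline report."""
    tables = {}
    space = report["niche"]["space"]
    tables["niche_axes"] = pd.DataFrame(
        {
            "axis": [f"pc{k+1}" for k in range(len(space.explained_fraction))],
            "explained_fraction": space.explained_fraction,
        }
    )
    tables["populations"] = report["niche"]["projection"].table
    rows = []
    for group, res in report["groups"].items():
        an = res["analysis"]
        a = an["assoc"]
        row = {
            "group": group,
            "tensor1_fraction": an["decomp"].fraction[0],
            "tensor2_fraction": an["decomp"].fraction[1]
            if len(an["decomp"].fraction) > 1
            else np.nan,
            "mantel_r": a.mantel_tensor.r,
            "mantel_p": a.mantel_tensor.p_value,
            "slope_tensor_median": a.slope_tensor.median,
            "slope_tensor_lo": a.slope_tensor.ci95[0],
            "slope_tensor_hi": a.slope_tensor.ci95[1],
            "slope_volume_median": an["slope_volume"].median,
            "slope_volume_lo": an["slope_volume"].ci95[0],
            "slope_volume_hi": an["slope_volume"].ci95[1],
        }
        if a.slope_angle is not None:
            row.update(
                slope_angle_median=a.slope_angle.median,
                slope_angle_lo=a.slope_angle.ci95[0],
                slope_angle_hi=a.slope_angle.ci95[1],
                mantel_angle_r=a.mantel_angle.r,
            )
        if "null" in res:
            row.update(
                slope_null_median=res["null"]["slope_null"].median,
                p_slope_vs_null=res["null"]["p_slope_vs_null"],
            )
        rows.append(row)
    tables["associations"] = pd.DataFrame(rows)

    rows = []
    for group, res in report["groups"].items():
        co = res["analysis"]["coords"]
        sub = co.intervals.copy()
        sub.insert(0, "group", group)
        rows.append(sub)
    tables["tensor_coordinates"] = pd.concat(rows, ignore_index=True)

    rows = []
    for group, res in report["groups"].items():
        for pop, gm in res["analysis"]["gmax"].items():
            s = gm.summary.copy()
            s.insert(0, "group", group)
            s.insert(1, "population", pop)
            rows.append(s)
    tables["gmax_summaries"] = pd.concat(rows, ignore_index=True)
    return tables
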