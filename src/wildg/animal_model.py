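"""Bayesian multivariate animal model.

Partitions multivariate phenotypic (co)variance into additive-genetic (G),
permanent-environment (PE), year (Y), observer (Obs, per-trait), and
residual (R) components with a Gibbs sampler, using the pedigree through
the sparse inverse relationship matrix.  Priors are slightly informative
inverse Wisharts: scale = diag(phenotypic variance / number of random
factors), degree of belief = number of traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._gibbs import gibbs_kernel


@dataclass
class ModelSpec:
    """Model structure for one trait group.

    age_mode: "quadratic" (centered age + age^2) or "classes" (factor).
    date_mode: None, "cubic" (centered date, date^2, date^3) or "periods".
    missing_covariates: "augment" (column-mean fill, quantitative only) or
    "delete" (drop record).  Missing categorical covariates always drop
    the record.
    """

    traits: list
    age_mode: str = "quadratic"
    use_sex: bool = False
    use_sex_age: bool = False
    date_mode: str | None = None
    use_pe: bool = True
    use_year: bool = True
    use_observer: bool = False
    missing_covariates: str = "augment"

    def __post_init__(self):
        if not self.traits:
            raise ValueError("ModelSpec needs at least one trait")
        if self.age_mode not in ("quadratic", "classes"):
            raise ValueError("age_mode must be 'quadratic' or 'classes'")
        if self.date_mode not in (None, "cubic", "periods"):
            raise ValueError("date_mode must be None, 'cubic' or 'periods'")
        if self.missing_covariates not in ("augment", "delete"):
            raise ValueError("missing_covariates must be 'augment' or 'delete'")

    @property
    def n_random_factors(self) -> int:
        """Random factors including the residual (prior-scale divisor)."""
        return 1 + int(self.use_pe) + int(self.use_year) + int(self.use_observer) + 1


@dataclass
class MCMCSettings:
    """Chain lengths.  The 'full' profile is 2e5 burn-in, 1e6 sampling
    iterations thinned every 1e3 (1,000 retained); the 'desk' profile is a
    shorter chain adequate for synthetic recovery work."""

    burnin: int = 5_000
    iterations: int = 50_000
    thin: int = 50
    seed: int = 0

    @property
    def retained(self) -> int:
        return self.iterations // self.thin

    @classmethod
    def profile(cls, name: str, seed: int = 0) -> "MCMCSettings":
        if name == "full":
            return cls(burnin=200_000, iterations=1_000_000, thin=1_000, seed=seed)
        if name == "desk":
            return cls(burnin=5_000, iterations=50_000, thin=50, seed=seed)
        if name == "smoke":
            return cls(burnin=1_000, iterations=6_000, thin=20, seed=seed)
        raise ValueError(f"unknown MCMC profile {name!r}")


@dataclass
class DesignBundle:
    """Prepared model inputs: response matrix, fixed design, factor codes."""

    Y: np.ndarray               # (nrec, T), NaN where missing
    X: np.ndarray               # (nrec, P)
    fixed_names: list
    ids: list                   # individual id per record
    year_codes: np.ndarray
    year_levels: list
    obs_codes: np.ndarray       # -1 where no observer
    obs_levels: list
    traits: list
    spec: ModelSpec
    phen_var: np.ndarray        # per-trait phenotypic variance (observed)

    @property
    def n_records(self) -> int:
        return len(self.ids)


@dataclass
class PosteriorSamples:
    """Retained posterior draws of all (co)variance components and fixed
    effects for one population x trait group fit."""

    traits: list
    G: np.ndarray               # (draws, T, T)
    PE: np.ndarray
    Y: np.ndarray
    R: np.ndarray
    obs_var: np.ndarray         # (draws, T)
    B: np.ndarray               # (draws, P, T)
    fixed_names: list
    phen_var: np.ndarray
    settings: MCMCSettings
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.G.shape[0]

    def component(self, name: str) -> np.ndarray:
        return {"G": self.G, "PE": self.PE, "Y": self.Y, "R": self.R}[name]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            for nm in ("G", "PE", "Y", "R", "obs_var", "B", "phen_var"):
                h.create_dataset(nm, data=getattr(self, nm))
            h.attrs["traits"] = [str(t) for t in self.traits]
            h.attrs["fixed_names"] = [str(t) for t in self.fixed_names]
            for k, v in asdict(self.settings).items():
                h.attrs[f"settings_{k}"] = v
            for k, v in self.meta.items():
                h.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        import h5py

        with h5py.File(path, "r") as h:
            kw = {nm: h[nm][...] for nm in ("G", "PE", "Y", "R", "obs_var", "B", "phen_var")}
            traits = [str(t) for t in h.attrs["traits"]]
            fixed_names = [str(t) for t in h.attrs["fixed_names"]]
            settings = MCMCSettings(
                burnin=int(h.attrs["settings_burnin"]),
                iterations=int(h.attrs["settings_iterations"]),
                thin=int(h.attrs["settings_thin"]),
                seed=int(h.attrs["settings_seed"]),
            )
            meta = {
                k[5:]: h.attrs[k] for k in h.attrs if k.startswith("meta_")
            }
        return cls(
            traits=traits, fixed_names=fixed_names, settings=settings, meta=meta, **kw
        )


def prior_scale(phen_var: np.ndarray, n_random_factors: int) -> np.ndarray:
    """Inverse-Wishart prior scale: diagonal of per-trait phenotypic
    variances divided by the number of random factors (residual included);
    the degree of belief is the number of traits."""
    return np.diag(np.asarray(phen_var, float) / n_random_factors)


# ------------------------------------------------------------------ design


def build_design(phenotypes: pd.DataFrame, spec: ModelSpec) -> DesignBundle:
    """Build fixed and random incidence structures from a phenotype table.

    Quantitative covariates with missing values are column-mean filled
    (average data augmentation) or their records dropped, per
    ``spec.missing_covariates``; records missing a categorical covariate
    are always dropped.
    """
    df = phenotypes.copy()
    for t in spec.traits:
        if t not in df.columns:
            raise ValueError(f"phenotype table lacks trait column {t!r}")

    quant = ["age"] + (["date"] if spec.date_mode == "cubic" else [])
    categ = []
    if spec.age_mode == "classes":
        quant.remove("age")
        categ.append("age")
    if spec.use_sex or spec.use_sex_age:
        categ.append("sex")
    if spec.date_mode == "periods":
        categ.append("date")
    if spec.use_year:
        categ.append("year")
    if spec.use_observer:
        categ.append("observer")

    for c in quant + categ:
        if c not in df.columns:
            raise ValueError(f"phenotype table lacks covariate column {c!r}")

    for c in quant:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            if spec.missing_covariates == "augment":
                col = col.fillna(col.mean())
            else:
                df = df[~col.isna()]
                col = col[~col.isna()]
        df[c] = col
    for c in categ:
        bad = df[c].isna() | (df[c].astype(str).isin(["", "NA", "nan"]))
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} record(s) with missing categorical {c!r}",
                stacklevel=2,
            )
            df = df[~bad]
    df = df.reset_index(drop=True)

    cols = [np.ones(len(df))]
    names = ["intercept"]
    if spec.age_mode == "quadratic":
        age_c = df["age"].to_numpy(float)
        age_c = age_c - age_c.mean()
        cols += [age_c, age_c**2]
        names += ["age", "age2"]
    else:
        levels = sorted(df["age"].astype(str).unique())
        for lv in levels[1:]:  # treatment contrasts, first level reference
            cols.append((df["age"].astype(str) == lv).to_numpy(float))
            names.append(f"age[{lv}]")
    if spec.use_sex:
        levels = sorted(df["sex"].astype(str).unique())
        for lv in levels[1:]:
            cols.append((df["sex"].astype(str) == lv).to_numpy(float))
            names.append(f"sex[{lv}]")
    if spec.use_sex_age:
        levels = sorted(df["sex"].astype(str).unique())
        age_c = df["age"].to_numpy(float)
        age_c = age_c - age_c.mean()
        for lv in levels[1:]:
            cols.append((df["sex"].astype(str) == lv).to_numpy(float) * age_c)
            names.append(f"sex[{lv}]:age")
    if spec.date_mode == "cubic":
        d = df["date"].to_numpy(float)
        d = d - d.mean()
        cols += [d, d**2, d**3]
        names += ["date", "date2", "date3"]
    elif spec.date_mode == "periods":
        per = pd.qcut(pd.to_numeric(df["date"]), 4, duplicates="drop").astype(str)
        for lv in sorted(per.unique())[1:]:
            cols.append((per == lv).to_numpy(float))
            names.append(f"date[{lv}]")
    X = np.column_stack(cols)

    Ymat = df[spec.traits].to_numpy(float)
    if spec.use_year:
        year_levels = sorted(df["year"].unique())
        ymap = {y: k for k, y in enumerate(year_levels)}
        year_codes = np.array([ymap[y] for y in df["year"]], dtype=np.int64)
    else:
        year_levels = []
        year_codes = np.full(len(df), -1, dtype=np.int64)
    if spec.use_observer:
        obs_levels = sorted(df["observer"].astype(str).unique())
        omap = {o: k for k, o in enumerate(obs_levels)}
        obs_codes = np.array([omap[str(o)] for o in df["observer"]], dtype=np.int64)
    else:
        obs_levels = []
        obs_codes = np.full(len(df), -1, dtype=np.int64)

    phen_var = np.nanvar(Ymat, axis=0, ddof=1)
    return DesignBundle(
        Y=Ymat,
        X=X,
        fixed_names=names,
        ids=[str(i) for i in df["id"]],
        year_codes=year_codes,
        year_levels=year_levels,
        obs_codes=obs_codes,
        obs_levels=obs_levels,
        traits=list(spec.traits),
        spec=spec,
        phen_var=phen_var,
    )


def _csr_lists(codes: np.ndarray, n_levels: int):
    """records grouped by level, CSR style."""
    order = np.argsort(codes, kind="stable")
    valid = order[codes[order] >= 0]
    counts = np.bincount(codes[codes >= 0], minlength=n_levels)
    rptr = np.zeros(n_levels + 1, dtype=np.int64)
    rptr[1:] = np.cumsum(counts)
    return rptr, valid.astype(np.int64)


def fit_animal_model(
    design: DesignBundle,
    ainverse: sp.spmatrix,
    spec: ModelSpec,
    settings: MCMCSettings,
    ped_ids: list,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return thinned posterior draws.

    ``ped_ids`` is the pedigree id order that indexes ``ainverse``; every
    phenotyped individual must appear in it.
    """
    n_ind = len(ped_ids)
    if ainverse.shape != (n_ind, n_ind):
        raise ValueError("A-inverse dimension does not match pedigree ids")
    pos = {iid: k for k, iid in enumerate(ped_ids)}
    try:
        rec_ind = np.array([pos[i] for i in design.ids], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"phenotyped individual {e} absent from pedigree") from e

    Y = design.Y
    nrec, T = Y.shape
    if nrec < design.X.shape[1]:
        raise ValueError(
            f"{nrec} records < {design.X.shape[1]} fixed-effect columns: not identifiable"
        )
    if not np.all(np.isfinite(design.X)):
        raise ValueError("non-finite values in the fixed design")
    miss = ~np.isfinite(Y)
    if miss.all(axis=0).any():
        raise ValueError("a trait has no observed values")
    Yw = np.where(miss, 0.0, Y)

    XtX = design.X.T @ design.X
    try:
        L_X = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular fixed-effect design (collinear columns)") from e

    n_year = max(len(design.year_levels), 1)
    n_obs = max(len(design.obs_levels), 1)
    ind_rptr, ind_rix = _csr_lists(rec_ind, n_ind)
    year_rptr, year_rix = _csr_lists(design.year_codes, n_year)
    obs_rptr, obs_rix = _csr_lists(design.obs_codes, n_obs)

    Ai = sp.csr_matrix(ainverse)
    Ai.sum_duplicates()

    nfac = spec.n_random_factors
    V0 = prior_scale(design.phen_var, nfac)
    s0_obs = design.phen_var / nfac
    nu0 = float(T)

    out = gibbs_kernel(
        int(settings.seed) % (2**31),
        int(settings.burnin),
        int(settings.iterations),
        int(settings.thin),
        np.ascontiguousarray(Yw, float),
        np.ascontiguousarray(miss),
        np.ascontiguousarray(design.X, float),
        np.ascontiguousarray(L_X, float),
        rec_ind,
        design.year_codes.astype(np.int64),
        design.obs_codes.astype(np.int64),
        ind_rptr,
        ind_rix,
        year_rptr,
        year_rix,
        obs_rptr,
        obs_rix,
        Ai.indptr.astype(np.int64),
        Ai.indices.astype(np.int64),
        np.ascontiguousarray(Ai.data, float),
        np.ascontiguousarray(V0, float),
        np.ascontiguousarray(V0, float),
        np.ascontiguousarray(V0, float),
        np.ascontiguousarray(V0, float),
        np.ascontiguousarray(s0_obs, float),
        nu0,
        int(spec.use_pe),
        int(spec.use_year),
        int(spec.use_observer),
    )
    G, PE, Yc, R, obs_var, B = out
    if not np.all(np.isfinite(G)):
        raise RuntimeError("non-finite posterior draws: degenerate data or model")
    return PosteriorSamples(
        traits=list(design.traits),
        G=G,
        PE=PE,
        Y=Yc,
        R=R,
        obs_var=obs_var,
        B=B,
        fixed_names=list(design.fixed_names),
        phen_var=design.phen_var,
        settings=settings,
        meta={"n_records": nrec, "n_individuals": n_ind},
    )


# ------------------------------------------------------------- diagnostics


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if np.ptp(x) == 0:  # constant series (e.g. a component not in the model)
        return 0.0
    x = x - x.mean()
    return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size."""
    x = np.asarray(x, float)
    n = len(x)
    if np.ptp(x) == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] < 0:
            break
        s += rho[k]
    return float(n / (1.0 + 2.0 * s))


def convergence_diagnostics(post: PosteriorSamples) -> pd.DataFrame:
    """Lag-1 autocorrelation and effective sample size for every
    (co)variance parameter; the fit passes when all |lag-1 rho| < 0.1."""
    if post.n_draws < 100:
        raise ValueError("need at least 100 retained draws for diagnostics")
    T = len(post.traits)
    rows = []
    for comp in ("G", "PE", "Y", "R"):
        M = post.component(comp)
        for i in range(T):
            for j in range(i, T):
                x = M[:, i, j]
                rows.append(
                    (
                        comp,
                        f"{post.traits[i]}:{post.traits[j]}",
                        _lag1_autocorr(x),
                        _ess(x),
                    )
                )
    for t in range(T):
        x = post.obs_var[:, t]
        rows.append(("Obs", post.traits[t], _lag1_autocorr(x), _ess(x)))
    rep = pd.DataFrame(rows, columns=["component", "parameter", "lag1_autocorr", "ess"])
    rep.attrs["passed"] = bool((rep["lag1_autocorr"].abs() < 0.1).all())
    return rep
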