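"""Founder-shuffling null model.

The null hypothesis is a single common G for all populations.  It is
simulated by drawing founder breeding values per population from that
population's posterior G, shuffling the pooled founder values across
populations, propagating breeding values down each pedigree under the
infinitesimal model (segregation covariance = randomized-G/2 times one
minus the mean parental inbreeding), recomposing phenotypes with the
original fit's fixed and non-genetic random effects, and refitting the
same animal model.  Every downstream comparison statistic can then be
referred to its null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .animal_model import DesignBundle, MCMCSettings, ModelSpec, PosteriorSamples, fit_animal_model
from .pedigree import UNKNOWN, Pedigree
from .simulate import _psd_project, psd_sqrt

logger = logging.getLogger(__name__)


@dataclass
class NullConfig:
    """Null-simulation scale: 1,000 replicates with 200 retained posterior
    samples per null fit at full scale; the desk profile trades replicates
    for wall time."""

    n_replicates: int = 1000
    posterior_subsample: int = 200
    mcmc: MCMCSettings = field(default_factory=lambda: MCMCSettings.profile("desk"))
    retry_cap: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1 or self.posterior_subsample < 1:
            raise ValueError("replicate and subsample counts must be >= 1")

    @classmethod
    def desk(cls, seed: int = 0) -> "NullConfig":
        return cls(
            n_replicates=50,
            posterior_subsample=100,
            mcmc=MCMCSettings.profile("desk", seed=seed),
            seed=seed,
        )


@dataclass
class NullGCollection:
    """Fitted null G draws per replicate and population."""

    populations: list
    traits: list
    replicates: list          # list of dict: population -> (subsample, T, T)
    provenance: pd.DataFrame  # replicate, posterior draw index, seed

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def mean_null_g(self) -> dict:
        """Per-population mean of the null-distribution G."""
        out = {}
        for p in self.populations:
            out[p] = np.mean(
                np.concatenate([rep[p] for rep in self.replicates]), axis=0
            )
        return out


def founder_bv_tables(
    fits: dict, peds: dict, draw: int, seed: int, traits: list
) -> dict:
    """Per-population founder breeding values drawn from that population's
    posterior G draw."""
    rng = np.random.default_rng(seed)
    out = {}
    for p, ped in peds.items():
        G = fits[p].G[draw]
        G = _psd_project(G, floor=0.0)
        mask = ped.founders()
        ids = [ped.ids[k] for k in np.where(mask)[0]]
        vals = rng.standard_normal((len(ids), G.shape[0])) @ psd_sqrt(G).T
        df = pd.DataFrame(vals, columns=traits)
        df.insert(0, "id", ids)
        out[p] = df
    return out


def shuffle_founder_bv(founder_bvs: dict, seed: int) -> dict:
    """Randomly reassign the pooled founder BV rows to founder slots across
    all populations; the pooled multiset of BV vectors is exactly preserved."""
    pops = list(founder_bvs.keys())
    traits = [c for c in founder_bvs[pops[0]].columns if c != "id"]
    counts = {p: len(founder_bvs[p]) for p in pops}
    pooled = np.concatenate([founder_bvs[p][traits].to_numpy(float) for p in pops])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pooled))
    shuffled = pooled[perm]
    out = {}
    k = 0
    for p in pops:
        n = counts[p]
        df = pd.DataFrame(shuffled[k : k + n], columns=traits)
        df.insert(0, "id", founder_bvs[p]["id"].to_numpy())
        out[p] = df
        k += n
    if k != len(pooled):
        raise RuntimeError("founder counts changed during shuffle")
    return out


def propagate_null_bv(
    ped: Pedigree, founder_bv: pd.DataFrame, F: np.ndarray, seed: int
) -> pd.DataFrame:
    """Propagate shuffled founder BVs down the pedigree.

    The randomized G is the sample covariance of the population's
    post-shuffle founder BVs; each non-founder's deviation has covariance
    randomized-G/2 * (1 - mean parental F), with an unknown parent
    contributing an extra randomized-G/4.
    """
    traits = [c for c in founder_bv.columns if c != "id"]
    T = len(traits)
    fmask = ped.founders()
    fidx = np.where(fmask)[0]
    fmap = dict(zip(founder_bv["id"], founder_bv[traits].to_numpy(float)))
    missing = [ped.ids[k] for k in fidx if ped.ids[k] not in fmap]
    if missing:
        raise ValueError(f"founder BVs missing for: {missing[:5]}")
    vals = founder_bv[traits].to_numpy(float)
    if len(vals) <= T:
        Grand = np.eye(T) * np.var(vals) if len(vals) else np.eye(T)
    else:
        Grand = np.cov(vals, rowvar=False)
    w = np.linalg.eigvalsh(0.5 * (Grand + Grand.T))
    if w.min() < -1e-12:
        import warnings

        warnings.warn("PSD-projecting randomized founder G", stacklevel=2)
        Grand = _psd_project(Grand, floor=0.0)
    L = psd_sqrt(Grand)

    rng = np.random.default_rng(seed)
    bv = np.zeros((ped.n, T))
    z = rng.standard_normal((ped.n, T))
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            bv[i] = fmap[ped.ids[i]]
            continue
        mean = np.zeros(T)
        fbar = 0.0
        extra = 0.0
        for p in (s, d):
            if p != UNKNOWN:
                mean += 0.5 * bv[p]
                fbar += 0.5 * F[p]
            else:
                extra += 0.25
        seg = 0.5 * (1.0 - fbar) + extra
        bv[i] = mean + np.sqrt(seg) * (L @ z[i])
    out = pd.DataFrame(bv, columns=traits)
    out.insert(0, "id", ped.ids)
    return out


def _recompose_matrix(
    bv: pd.DataFrame, fit: PosteriorSamples, draw: int, design: DesignBundle, seed: int
) -> np.ndarray:
    """New response matrix: fixed part from the stored design and the
    posterior fixed-effect draw, plus simulated BVs and fresh PE / year /
    observer / residual draws from that same posterior draw's matrices."""
    traits = list(fit.traits)
    T = len(traits)
    rng = np.random.default_rng(seed)
    bmap = {i: k for k, i in enumerate(bv["id"])}
    try:
        rows = np.array([bmap[i] for i in design.ids])
    except KeyError as e:
        raise ValueError(f"record individual {e} missing from BV table") from e
    bvm = bv[traits].to_numpy(float)[rows]
    fixed = design.X @ fit.B[draw]

    def _mvn(cov, size):
        return rng.standard_normal((size, T)) @ psd_sqrt(cov).T

    Ynew = fixed + bvm + _mvn(fit.R[draw], len(design.ids))
    spec = design.spec
    if spec.use_pe:
        uniq = sorted(set(design.ids))
        pe = _mvn(fit.PE[draw], len(uniq))
        pmap = {i: k for k, i in enumerate(uniq)}
        Ynew += pe[[pmap[i] for i in design.ids]]
    if spec.use_year and len(design.year_levels):
        yr = _mvn(fit.Y[draw], len(design.year_levels))
        Ynew += yr[design.year_codes]
    if spec.use_observer and len(design.obs_levels):
        ob = rng.standard_normal((len(design.obs_levels), T)) * np.sqrt(
            np.maximum(fit.obs_var[draw], 0.0)
        )
        Ynew += ob[design.obs_codes]
    return Ynew


def recompose_phenotypes(
    bv: pd.DataFrame, fit: PosteriorSamples, draw: int, design: DesignBundle, seed: int
) -> pd.DataFrame:
    """Null phenotype table for one posterior draw (record covariate levels
    come from the stored design bundle)."""
    if list(bv.columns[1:]) != list(fit.traits):
        raise ValueError("BV trait columns do not match the fit's traits")
    Ynew = _recompose_matrix(bv, fit, draw, design, seed)
    out = pd.DataFrame(Ynew, columns=fit.traits)
    out.insert(0, "id", design.ids)
    out.insert(
        1,
        "year",
        [design.year_levels[c] if c >= 0 else "NA" for c in design.year_codes],
    )
    out.insert(
        2,
        "observer",
        [design.obs_levels[c] if c >= 0 else "NA" for c in design.obs_codes],
    )
    return out


def run_null(
    fits: dict,
    peds: dict,
    designs: dict,
    ainverses: dict,
    inbreedings: dict,
    spec: ModelSpec,
    cfg: NullConfig,
) -> NullGCollection:
    """Full null simulation: per replicate, pick one posterior draw, draw
    and shuffle founder BVs across populations, propagate, recompose, and
    refit each population with the same model."""
    pops = list(fits.keys())
    traits = list(fits[pops[0]].traits)
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = ss.spawn(cfg.n_replicates)
    n_draws = min(fits[p].n_draws for p in pops)
    replicates = []
    prov = []
    for r in range(cfg.n_replicates):
        for attempt in range(cfg.retry_cap):
            try:
                child = np.random.SeedSequence(
                    entropy=rep_seeds[r].entropy,
                    spawn_key=rep_seeds[r].spawn_key + (attempt,),
                )
                rng = np.random.default_rng(child)
                draw = int(rng.integers(n_draws))
                base = int(rng.integers(2**31))
                founders = founder_bv_tables(fits, peds, draw, base, traits)
                shuffled = shuffle_founder_bv(founders, base + 1)
                rep_out = {}
                for j, p in enumerate(pops):
                    bv = propagate_null_bv(
                        peds[p], shuffled[p], inbreedings[p], base + 2 + j
                    )
                    Ynew = _recompose_matrix(
                        bv, fits[p], draw, designs[p], base + 100 + j
                    )
                    nd = dc_replace(designs[p], Y=Ynew)
                    settings = dc_replace(cfg.mcmc, seed=base + 200 + j)
                    post = fit_animal_model(
                        nd, ainverses[p], spec, settings, peds[p].ids
                    )
                    keep = min(cfg.posterior_subsample, post.n_draws)
                    idx = np.linspace(0, post.n_draws - 1, keep).astype(int)
                    rep_out[p] = post.G[idx]
                replicates.append(rep_out)
                prov.append((r, draw, base))
                break
            except Exception as e:  # re-drawn up to the retry cap
                logger.warning("null replicate %d attempt %d failed: %s", r, attempt, e)
        else:
            raise RuntimeError(f"null replicate {r} failed {cfg.retry_cap} times")
    return NullGCollection(
        populations=pops,
        traits=traits,
        replicates=replicates,
        provenance=pd.DataFrame(prov, columns=["replicate", "posterior_draw", "seed"]),
    )


def null_standardized_gsets(collection: NullGCollection, ndraw_vabar: int = 200):
    """Standardize each null replicate's G set by its own interpopulation
    Va-bar, mirroring the treatment of the observed set."""
    from .standardize import estimate_vabar, standardize_draws

    out = []
    for r, rep in enumerate(collection.replicates):
        vb = estimate_vabar(rep, ndraw=ndraw_vabar, seed=1000 + r)
        out.append(standardize_draws(rep, collection.traits, vb))
    return out


def null_distance_draws(null_gsets: list, k: int = 2) -> np.ndarray:
    """Per-draw tensor distances pooled across null replicates, each
    replicate analysed in its own eigentensor space."""
    from .tensor import build_tensor, coordinates, tensor_distances

    mats = []
    for gs in null_gsets:
        decomp = build_tensor(gs)
        co = coordinates(gs, decomp, n_axes=min(k, decomp.eigentensors.shape[0]))
        dset = tensor_distances(co, k=min(k, co.n_axes))
        mats.append(dset.draws)
    return np.concatenate(mats, axis=0)
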