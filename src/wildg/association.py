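"""Distance-based association between G-matrix divergence and climate.

Mantel permutation tests between distance matrices; slope posteriors from
per-draw or replicate-shuffled regressions of tensor (or angle) distances
on niche distances; one-sided data-vs-null slope comparisons; and
regressions of per-population posterior scalars (standardized Va, volume)
on a gradient such as the distance to the niche center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _as_square(d) -> np.ndarray:
    D = d.to_numpy(float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return D


def _upper(D: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(D.shape[0], k=1)
    return D[i, j]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int
    alternative: str


@dataclass
class SlopePosterior:
    """Empirical slope distribution with its 95% interval."""

    slopes: np.ndarray
    predictor: str = ""

    def __post_init__(self):
        self.slopes = np.asarray(self.slopes, float)

    @property
    def ci95(self) -> tuple:
        return (
            float(np.quantile(self.slopes, 0.025)),
            float(np.quantile(self.slopes, 0.975)),
        )

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return bool(lo > 0 or hi < 0)

    @property
    def median(self) -> float:
        return float(np.median(self.slopes))


def mantel(dA, dB, n_perm: int = 9999, seed: int = 0, alternative: str = "greater") -> MantelResult:
    """Mantel test: Pearson r of off-diagonal upper triangles; p from
    joint row/column permutations of dB, p = (1 + #{r_perm >= r}) / (n_perm + 1)."""
    DA = _as_square(dA)
    DB = _as_square(dB)
    if DA.shape != DB.shape:
        raise ValueError("distance matrices differ in dimension")
    xa = _upper(DA)
    if xa.std() == 0 or _upper(DB).std() == 0:
        raise ValueError("constant off-diagonal entries: correlation undefined")
    m = DA.shape[0]
    rng = np.random.default_rng(seed)
    xa_c = (xa - xa.mean()) / xa.std()

    def _corr(entries):
        xb = (entries - entries.mean(-1, keepdims=True)) / entries.std(-1, keepdims=True)
        return np.mean(xa_c * xb, axis=-1)

    iu, ju = np.triu_indices(m, k=1)
    r_obs = float(_corr(DB[iu, ju]))
    perms = np.stack([rng.permutation(m) for _ in range(n_perm)])
    entries = DB[perms[:, iu], perms[:, ju]]  # (n_perm, n_pairs)
    rp = _corr(entries)
    if alternative == "greater":
        count = int(np.sum(rp >= r_obs))
    elif alternative == "less":
        count = int(np.sum(rp <= r_obs))
    else:
        count = int(np.sum(np.abs(rp) >= abs(r_obs)))
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, seed=seed, alternative=alternative)


def _ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def shuffle_distance_replicates(draws: np.ndarray, seed: int) -> np.ndarray:
    """Independently permute each pair's distance values across the
    replicate axis, breaking inter-pair dependence while preserving each
    pair's marginal multiset exactly."""
    draws = np.asarray(draws, float)
    nrep, m, _ = draws.shape
    rng = np.random.default_rng(seed)
    out = draws.copy()
    iu, ju = np.triu_indices(m, k=1)
    for i, j in zip(iu, ju):
        perm = rng.permutation(nrep)
        out[:, i, j] = draws[perm, i, j]
        out[:, j, i] = out[:, i, j]
    return out


def randomized_distance_regression(
    dset, predictor, seed: int = 0, shuffle: bool = True
) -> SlopePosterior:
    """Regress replicate distance matrices (rows/cols populations) on a
    predictor distance matrix, pair-shuffled across replicates first.

    ``dset`` may be a TensorDistanceSet or an (nrep, m, m) array.  Each
    replicate contributes one OLS slope over the m(m-1)/2 pairs."""
    draws = dset.draws if hasattr(dset, "draws") else np.asarray(dset, float)
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 replicate distance matrices")
    P = _as_square(predictor)
    if P.shape[0] != draws.shape[1]:
        raise ValueError("predictor dimension does not match distance replicates")
    xp = _upper(P)
    if xp.std() == 0:
        raise ValueError("constant predictor")
    work = shuffle_distance_replicates(draws, seed) if shuffle else draws
    slopes = np.array([_ols_slope(_upper(work[t]), xp) for t in range(work.shape[0])])
    return SlopePosterior(slopes=slopes, predictor="distance predictor")


def slope_comparison(data: SlopePosterior, null: SlopePosterior, seed: int = 0, n_pairs: int = 10000) -> float:
    """One-sided p: proportion of randomly paired draws where the null
    slope is >= the data slope."""
    rng = np.random.default_rng(seed)
    a = rng.choice(data.slopes, size=n_pairs, replace=True)
    b = rng.choice(null.slopes, size=n_pairs, replace=True)
    return float(np.mean(b >= a))


def posterior_vs_gradient(posterior_scalars: dict, predictor: dict | pd.Series) -> SlopePosterior:
    """Per-draw OLS of m populations' posterior scalars on a per-population
    predictor; the draw-wise slopes form the posterior."""
    pops = list(posterior_scalars.keys())
    if len(pops) < 3:
        raise ValueError("need at least 3 populations for a slope")
    x = np.array([float(predictor[p]) for p in pops])
    nd = min(len(np.asarray(posterior_scalars[p]).ravel()) for p in pops)
    mat = np.stack([np.asarray(posterior_scalars[p], float).ravel()[:nd] for p in pops])
    slopes = np.array([_ols_slope(mat[:, t], x) for t in range(nd)])
    return SlopePosterior(slopes=slopes, predictor="gradient")


@dataclass
class AssociationBundle:
    """All association statistics for one trait group, recomputable on a
    population subset."""

    populations: list
    mantel_tensor: MantelResult
    slope_tensor: SlopePosterior
    mantel_angle: MantelResult | None
    slope_angle: SlopePosterior | None
    dropped: tuple = ()


def associate(
    gset,
    niche_d: pd.DataFrame,
    seed: int = 0,
    n_perm: int = 999,
    k_axes: int = 2,
    with_angles: bool = True,
) -> AssociationBundle:
    """Tensor build -> coordinates -> distances -> Mantel + randomized
    regression, plus the g_max-angle analogues, for one standardized G set."""
    from .tensor import build_tensor, coordinates, tensor_distances
    from .geometry import _pairwise_angles

    pops = gset.populations
    D = niche_d.loc[pops, pops]
    decomp = build_tensor(gset)
    coords = coordinates(gset, decomp, n_axes=min(k_axes, decomp.eigentensors.shape[0]))
    dset = tensor_distances(coords, k=min(k_axes, coords.n_axes))
    man = mantel(pd.DataFrame(dset.mode, index=pops, columns=pops), D, n_perm=n_perm, seed=seed)
    slope = randomized_distance_regression(dset, D, seed=seed + 1)

    man_a = slope_a = None
    if with_angles:
        from .geometry import gmax_summary

        gm = {p: gmax_summary(gset.draws[p], gset.traits) for p in pops}
        nd = min(gm[p].gmax_draws.shape[0] for p in pops)
        m = len(pops)
        ang_draws = np.zeros((nd, m, m))
        for i in range(m):
            for j in range(i + 1, m):
                a = _pairwise_angles(
                    gm[pops[i]].gmax_draws[:nd], gm[pops[j]].gmax_draws[:nd]
                )
                ang_draws[:, i, j] = a
                ang_draws[:, j, i] = a
        from .tensor import posterior_mode as _pm

        mode = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                mode[i, j] = mode[j, i] = _pm(ang_draws[:, i, j])
        man_a = mantel(pd.DataFrame(mode, index=pops, columns=pops), D, n_perm=n_perm, seed=seed + 2)
        slope_a = randomized_distance_regression(ang_draws, D, seed=seed + 3)
    return AssociationBundle(
        populations=list(pops),
        mantel_tensor=man,
        slope_tensor=slope,
        mantel_angle=man_a,
        slope_angle=slope_a,
    )


def leave_out_rerun(
    gset, niche_d: pd.DataFrame, drop, seed: int = 0, n_perm: int = 999, with_angles: bool = True
) -> AssociationBundle:
    """Recompute the association bundle with a population subset removed
    (the tensor decomposition is rebuilt upstream on the reduced set)."""
    drop = tuple(drop)
    keep = [p for p in gset.populations if p not in drop]
    if len(keep) < 3:
        raise ValueError("fewer than 3 populations would remain")
    sub = gset.subset(keep)
    bundle = associate(sub, niche_d.loc[keep, keep], seed=seed, n_perm=n_perm, with_angles=with_angles)
    bundle.dropped = drop
    return bundle
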