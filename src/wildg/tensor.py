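"""Genetic covariance tensor analysis.

The set of m standardized G-matrices is compared by vectorizing each
symmetric n x n matrix into a length n(n+1)/2 vector (off-diagonals scaled
by sqrt 2 so Euclidean and Frobenius inner products coincide), forming the
q x q covariance matrix S of the populations' vectors, and
eigen-decomposing S.  The eigenvectors devectorize into orthonormal
"eigentensors" — matrix directions along which the G set varies most —
with eigenvalues alpha giving the magnitude of among-population variation
captured by each.  Each eigentensor eigen-decomposes further into trait
eigenvectors showing which trait combinations drive that axis of change.
Posterior uncertainty is propagated by rebuilding S from each posterior
draw and projecting it through the fixed eigentensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .standardize import StandardizedGSet


def posterior_mode(x: np.ndarray) -> float:
    """Kernel-density posterior mode (Silverman bandwidth), evaluated at
    the sample points."""
    x = np.asarray(x, float)
    if len(x) < 3 or np.ptp(x) == 0:
        return float(np.median(x))
    kde = gaussian_kde(x, bw_method="silverman")
    return float(x[np.argmax(kde(x))])


def credible_interval(x: np.ndarray, level: float) -> tuple:
    lo = np.quantile(x, (1 - level) / 2)
    hi = np.quantile(x, 1 - (1 - level) / 2)
    return float(lo), float(hi)


# ------------------------------------------------------------ vectorization


def vectorize_g(G: np.ndarray) -> np.ndarray:
    """Symmetric matrix -> vector: diagonals first, then upper-triangle
    rows scaled by sqrt 2 (so <v1, v2> = <G1, G2>_Frobenius)."""
    G = np.asarray(G, float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    n = G.shape[0]
    parts = [np.diag(G)]
    off = [G[i, j] * np.sqrt(2.0) for i in range(n) for j in range(i + 1, n)]
    return np.concatenate([parts[0], np.asarray(off)])


def devectorize_g(v: np.ndarray, n: int) -> np.ndarray:
    v = np.asarray(v, float)
    if len(v) != n * (n + 1) // 2:
        raise ValueError("vector length does not match matrix dimension")
    G = np.diag(v[:n]).astype(float)
    k = n
    for i in range(n):
        for j in range(i + 1, n):
            G[i, j] = G[j, i] = v[k] / np.sqrt(2.0)
            k += 1
    return G


# ------------------------------------------------------------ decomposition


@dataclass
class CovarianceTensorDecomposition:
    traits: list
    populations: list
    S: np.ndarray                    # (q, q) covariance of vectorized Gs
    alphas: np.ndarray               # eigenvalues, descending
    eigentensors: np.ndarray         # (q_axes, n, n), unit Frobenius norm
    fraction: np.ndarray             # point fraction of variance per axis
    fraction_draws: np.ndarray       # (ndraws, q_axes) posterior fractions

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def _vectorized_set(gset: StandardizedGSet):
    pops = gset.populations
    n = len(gset.traits)
    ndraws = min(gset.draws[p].shape[0] for p in pops)
    Vmean = np.stack([vectorize_g(gset.posterior_mean(p)) for p in pops])
    Vdraws = np.stack(
        [[vectorize_g(gset.draws[p][t]) for p in pops] for t in range(ndraws)]
    )  # (ndraws, m, q)
    return Vmean, Vdraws


def build_tensor(gset: StandardizedGSet) -> CovarianceTensorDecomposition:
    """Eigen-decomposition of S = cov (denominator m-1) of the populations'
    posterior-mean vectorized Gs; per-draw fractions by projecting each
    draw's S_t through the fixed eigentensors."""
    pops = gset.populations
    if len(pops) < 2:
        raise ValueError("tensor comparison needs at least 2 populations")
    counts = {gset.draws[p].shape[0] for p in pops}
    if len(counts) > 1:
        import warnings

        warnings.warn(
            "mismatched draw counts across populations; truncating to the minimum",
            stacklevel=2,
        )
    n = len(gset.traits)
    Vmean, Vdraws = _vectorized_set(gset)
    S = np.cov(Vmean.T, ddof=1)
    S = np.atleast_2d(S)
    w, E = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    E = E[:, order]
    tensors = []
    for k in range(E.shape[1]):
        Ek = devectorize_g(E[:, k], n)
        # sign: largest-magnitude trait loading of the leading eigenvector positive
        lam, vec = np.linalg.eigh(Ek)
        lead = vec[:, np.argmax(np.abs(lam))]
        if lead[np.argmax(np.abs(lead))] < 0:
            lead = -lead
        if np.sum(lead * (Ek @ lead)) < 0:
            Ek = -Ek
        tensors.append(Ek)
    tensors = np.stack(tensors)
    frac = w / w.sum() if w.sum() > 0 else np.zeros_like(w)

    ndraws = Vdraws.shape[0]
    fr_draws = np.zeros((ndraws, len(w)))
    for t in range(ndraws):
        St = np.atleast_2d(np.cov(Vdraws[t].T, ddof=1))
        tr = np.trace(St)
        if tr <= 0:
            continue
        for k in range(len(w)):
            ek = E[:, k]
            fr_draws[t, k] = ek @ St @ ek / tr
    return CovarianceTensorDecomposition(
        traits=list(gset.traits),
        populations=list(pops),
        S=S,
        alphas=w,
        eigentensors=tensors,
        fraction=frac,
        fraction_draws=fr_draws,
    )


# -------------------------------------------------------------- coordinates


@dataclass
class CoordinateTable:
    populations: list
    draws: np.ndarray       # (ndraws, m, n_axes) Frobenius coordinates
    mode: np.ndarray        # (m, n_axes) posterior modes
    intervals: pd.DataFrame  # population x axis x level rows

    @property
    def n_axes(self) -> int:
        return self.draws.shape[2]


def coordinates(
    gset: StandardizedGSet, decomp: CovarianceTensorDecomposition, n_axes: int | None = None
) -> CoordinateTable:
    """Coordinate of draw t of population k on eigentensor i: the
    Frobenius inner product <G_kt, E_i>."""
    if list(gset.traits) != list(decomp.traits):
        raise ValueError("trait order mismatch between G set and decomposition")
    pops = gset.populations
    n_axes = n_axes or decomp.eigentensors.shape[0]
    ndraws = min(gset.draws[p].shape[0] for p in pops)
    out = np.zeros((ndraws, len(pops), n_axes))
    for j, p in enumerate(pops):
        D = gset.draws[p][:ndraws]
        for i in range(n_axes):
            out[:, j, i] = np.tensordot(D, decomp.eigentensors[i], axes=([1, 2], [0, 1]))
    mode = np.zeros((len(pops), n_axes))
    rows = []
    for j, p in enumerate(pops):
        for i in range(n_axes):
            x = out[:, j, i]
            mode[j, i] = posterior_mode(x)
            for level in (0.5, 0.75, 0.95):
                lo, hi = credible_interval(x, level)
                rows.append((p, i + 1, level, mode[j, i], lo, hi))
    intervals = pd.DataFrame(
        rows, columns=["population", "eigentensor", "level", "mode", "lo", "hi"]
    )
    return CoordinateTable(populations=list(pops), draws=out, mode=mode, intervals=intervals)


def eigentensor_traits(decomp: CovarianceTensorDecomposition, i: int) -> pd.DataFrame:
    """Trait eigenvectors of eigentensor i with eigenvalues and
    fraction-of-variation shares (lambda^2, summing to 1 for a unit-
    Frobenius-norm eigentensor)."""
    E = decomp.eigentensors[i]
    lam, vec = np.linalg.eigh(E)
    order = np.argsort(np.abs(lam))[::-1]
    lam = lam[order]
    vec = vec[:, order]
    norm = np.sum(lam**2)
    rows = []
    for k in range(len(lam)):
        v = vec[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        share = lam[k] ** 2 / norm if norm > 0 else 0.0
        rows.append(
            {
                "eigenvector": k + 1,
                "eigenvalue": lam[k],
                "share": share,
                **{f"loading_{t}": v[j] for j, t in enumerate(decomp.traits)},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- distances


@dataclass
class TensorDistanceSet:
    populations: list
    draws: np.ndarray   # (ndraws, m, m)
    mode: np.ndarray    # (m, m) from posterior-mode coordinates


def tensor_distances(coords: CoordinateTable, k: int = 2) -> TensorDistanceSet:
    """Euclidean distances among populations in the first k eigentensor
    coordinates, per posterior draw and at the posterior-mode coordinates."""
    if k > coords.n_axes:
        raise ValueError(f"k={k} exceeds available eigentensor axes")

    def _dist(xy):
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    draws = np.stack([_dist(coords.draws[t, :, :k]) for t in range(coords.draws.shape[0])])
    mode = _dist(coords.mode[:, :k])
    return TensorDistanceSet(populations=list(coords.populations), draws=draws, mode=mode)


# --------------------------------------------------------------- null tests


def tensor_null_pvalues(
    decomp: CovarianceTensorDecomposition, null_gsets: list
) -> pd.DataFrame:
    """Empirical p per eigentensor rank: the proportion of null-replicate
    G sets whose rank-i eigenvalue fraction is >= the observed fraction."""
    if len(null_gsets) < 20:
        raise ValueError("need at least 20 null replicate G sets")
    obs = decomp.fraction
    null_fracs = []
    for gs in null_gsets:
        d = build_tensor(gs)
        f = np.zeros_like(obs)
        f[: len(d.fraction)] = d.fraction[: len(obs)]
        null_fracs.append(f)
    null_fracs = np.stack(null_fracs)
    n = len(null_gsets)
    rows = []
    for i in range(len(obs)):
        ge = int(np.sum(null_fracs[:, i] >= obs[i]))
        p = ge / n
        rows.append((i + 1, obs[i], p, max(p, 1.0 / n) if ge == 0 else p, n))
    out = pd.DataFrame(
        rows, columns=["eigentensor", "observed_fraction", "p_value", "p_reported", "n_null"]
    )
    return out
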