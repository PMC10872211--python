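"""Size, shape, and orientation of single G-matrices.

g_max is the leading eigenvector (direction of most genetic variance, the
"line of least resistance"); eccentricity is the leading eigenvalue over
the eigenvalue sum (how concentrated variance is along g_max); volume is
the eigenvalue sum (= trace, total genetic variance).  Orientation
divergence between two populations is tested by comparing the posterior
between-population angle distribution with each population's own
within-posterior angle variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tensor import credible_interval, posterior_mode

DEGENERACY_TOL = 1e-8


@dataclass
class GmaxSummary:
    traits: list
    gmax: np.ndarray              # posterior-aligned mean direction, unit norm
    gmax_draws: np.ndarray        # (ndraws, T) sign-aligned
    leading_eigenvalue: np.ndarray  # (ndraws,)
    eccentricity: np.ndarray
    volume: np.ndarray
    degenerate: bool = False
    summary: pd.DataFrame = field(default=None, repr=False)


def gmax_summary(draws: np.ndarray, traits: list | None = None) -> GmaxSummary:
    """Per-draw eigen-decomposition of posterior G draws.

    g_max signs are aligned to the posterior-mean leading eigenvector so
    posterior spread is not inflated by arbitrary eigenvector sign flips.
    A near-isotropic posterior mean (top two eigenvalues within tolerance)
    is flagged degenerate.
    """
    draws = np.asarray(draws, float)
    if draws.ndim == 2:
        draws = draws[None, :, :]
    nd, T, _ = draws.shape
    if not np.allclose(draws, np.transpose(draws, (0, 2, 1)), atol=1e-8):
        raise ValueError("non-symmetric G draw")
    traits = list(traits) if traits is not None else [f"trait{k+1}" for k in range(T)]

    Gbar = draws.mean(axis=0)
    wbar, Vbar = np.linalg.eigh(Gbar)
    ref = Vbar[:, -1]
    degenerate = bool(wbar[-1] - wbar[-2] < DEGENERACY_TOL) if T > 1 else False
    if ref[np.argmax(np.abs(ref))] < 0:
        ref = -ref

    gmax_draws = np.zeros((nd, T))
    lead = np.zeros(nd)
    ecc = np.zeros(nd)
    vol = np.zeros(nd)
    for t in range(nd):
        w, V = np.linalg.eigh(draws[t])
        v1 = V[:, -1]
        if np.dot(v1, ref) < 0:
            v1 = -v1
        gmax_draws[t] = v1
        lead[t] = w[-1]
        tot = w.sum()
        ecc[t] = w[-1] / tot if tot > 0 else 1.0 / T
        vol[t] = tot

    rows = []
    for name, x in (
        ("leading_eigenvalue", lead),
        ("eccentricity", ecc),
        ("volume", vol),
    ):
        entry = {"statistic": name, "mode": posterior_mode(x)}
        for level in (0.5, 0.75, 0.95):
            lo, hi = credible_interval(x, level)
            entry[f"lo{int(level*100)}"] = lo
            entry[f"hi{int(level*100)}"] = hi
        rows.append(entry)
    return GmaxSummary(
        traits=traits,
        gmax=ref,
        gmax_draws=gmax_draws,
        leading_eigenvalue=lead,
        eccentricity=ecc,
        volume=vol,
        degenerate=degenerate,
        summary=pd.DataFrame(rows),
    )


def angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two trait-space directions in degrees, in [0, 90]
    (eigenvector sign is meaningless, so the absolute dot product is used)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    c = abs(np.dot(u, v)) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _pairwise_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    c = np.abs(np.einsum("ij,ij->i", A, B))
    norm = np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1)
    return np.degrees(np.arccos(np.clip(c / norm, -1.0, 1.0)))


def gmax_divergence_test(
    postA: np.ndarray, postB: np.ndarray, seed: int = 0
) -> dict:
    """Compare between-population g_max angles with each population's
    within-posterior angle variation.

    Divergence is supported when the posterior median between angle
    exceeds the 95th percentile of both within distributions (angles
    between independent draw pairs of the same posterior).
    """
    postA = np.asarray(postA, float)
    postB = np.asarray(postB, float)
    if len(postA) < 100 or len(postB) < 100:
        raise ValueError("need at least 100 posterior g_max draws per population")
    rng = np.random.default_rng(seed)
    n = min(len(postA), len(postB))
    ia = rng.permutation(len(postA))[:n]
    ib = rng.permutation(len(postB))[:n]
    between = _pairwise_angles(postA[ia], postB[ib])

    def _within(P):
        i = rng.permutation(len(P))
        j = rng.permutation(len(P))
        keep = i != j
        return _pairwise_angles(P[i[keep]], P[j[keep]])

    withinA = _within(postA)
    withinB = _within(postB)
    med = float(np.median(between))
    support = bool(
        med > np.percentile(withinA, 95) and med > np.percentile(withinB, 95)
    )
    return {
        "between": between,
        "within_a": withinA,
        "within_b": withinB,
        "median_between": med,
        "support": support,
    }
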