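"""Interpopulation Va-bar standardization of G posteriors.

All comparisons operate on G-matrices divided elementwise by
sqrt(Vabar_i * Vabar_j), where Vabar_t is the interpopulation mean
additive genetic variance of trait t.  Within a trait every population is
divided by the same constant, so cross-population variance ratios are
untouched and genetic correlations are preserved draw by draw; a
standardized variance above one means the population holds more genetic
variance than the species average for that trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .animal_model import PosteriorSamples


@dataclass
class VaBar:
    """Per-trait interpopulation mean additive genetic variance."""

    traits: list
    values: np.ndarray
    ndraw: int
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values <= 0):
            raise ValueError("Va-bar must be strictly positive per trait")


@dataclass
class StandardizedGSet:
    """Per-population standardized G draws on a shared trait order."""

    traits: list
    draws: dict        # population -> (ndraws, T, T)
    vabar: VaBar

    @property
    def populations(self) -> list:
        return list(self.draws.keys())

    def posterior_mean(self, pop) -> np.ndarray:
        return self.draws[pop].mean(axis=0)

    def subset(self, pops) -> "StandardizedGSet":
        return StandardizedGSet(
            traits=self.traits,
            draws={p: self.draws[p] for p in pops},
            vabar=self.vabar,
        )


def _repair_psd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    if w.min() < 0:
        warnings.warn("clipping negative eigenvalue in a posterior G draw", stacklevel=2)
        w = np.maximum(w, 0.0)
    return (V * w) @ V.T


def estimate_vabar(
    posteriors: dict, ndraw: int = 1000, seed: int = 0
) -> VaBar:
    """Monte Carlo Va-bar: for each posterior draw of each population's G,
    draw ``ndraw`` zero-mean multivariate-normal deviates; Vabar_t is the
    variance of coordinate t over all pooled deviates.

    (The analytic limit is the equal-weight mean over populations of the
    mean posterior Va per trait; the resampling route matches the stated
    estimation procedure and converges to it.)
    """
    pops = list(posteriors.keys())
    if not pops:
        raise ValueError("no posteriors supplied")

    def _gdraws(p):
        obj = posteriors[p]
        return obj.G if hasattr(obj, "G") else np.asarray(obj, float)

    first = posteriors[pops[0]]
    traits = (
        list(first.traits)
        if hasattr(first, "traits")
        else [f"trait{k+1}" for k in range(_gdraws(pops[0]).shape[-1])]
    )
    for p in pops:
        obj = posteriors[p]
        if hasattr(obj, "traits") and list(obj.traits) != traits:
            raise ValueError("populations do not share a trait order")
        if len(_gdraws(p)) == 0:
            raise ValueError(f"empty posterior for population {p!r}")
    T = len(traits)
    rng = np.random.default_rng(seed)
    # pooled variance via moment accumulation (means are zero by construction)
    ssq = np.zeros(T)
    count = 0
    for p in pops:
        for Gd in _gdraws(p):
            w, V = np.linalg.eigh(0.5 * (Gd + Gd.T))
            if w.min() < -1e-10:
                Gd = _repair_psd(Gd)
                w, V = np.linalg.eigh(Gd)
            w = np.maximum(w, 0.0)
            L = V * np.sqrt(w)
            z = rng.standard_normal((ndraw, T))
            x = z @ L.T
            ssq += (x**2).sum(axis=0)
            count += ndraw
    values = ssq / (count - 1)
    return VaBar(traits=traits, values=values, ndraw=ndraw, seed=seed)


def standardize_g(posteriors: dict, vabar: VaBar) -> StandardizedGSet:
    """Divide element (i, j) of every G draw by sqrt(Vabar_i * Vabar_j)."""
    pops = list(posteriors.keys())
    traits = list(posteriors[pops[0]].traits)
    if list(vabar.traits) != traits:
        raise ValueError("Va-bar trait order does not match posteriors")
    if np.any(vabar.values <= 0):
        raise ValueError("Va-bar has non-positive components")
    denom = np.sqrt(np.outer(vabar.values, vabar.values))
    draws = {}
    for p in pops:
        if list(posteriors[p].traits) != traits:
            raise ValueError("populations do not share a trait order")
        draws[p] = posteriors[p].G / denom[None, :, :]
    return StandardizedGSet(traits=traits, draws=draws, vabar=vabar)


def standardize_draws(draws: dict, traits: list, vabar: VaBar) -> StandardizedGSet:
    """Standardize raw draw arrays (population -> (n, T, T)) directly;
    convenience for null-model G collections."""
    denom = np.sqrt(np.outer(vabar.values, vabar.values))
    return StandardizedGSet(
        traits=list(traits),
        draws={p: np.asarray(d) / denom[None, :, :] for p, d in draws.items()},
        vabar=vabar,
    )
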