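import numpy as np
import pytest

from wildg.standardize import StandardizedGSet, VaBar
from wildg.tensor import (
    build_tensor,
    coordinates,
    devectorize_g,
    eigentensor_traits,
    tensor_distances,
    tensor_null_pvalues,
    vectorize_g,
)

from .conftest import random_psd


def _gset(draws_by_pop, traits=None):
    pops = list(draws_by_pop)
    n = np.asarray(draws_by_pop[pops[0]]).shape[-1]
    traits = traits or [f"t{k+1}" for k in range(n)]
    vb = VaBar(traits=traits, values=np.ones(n), ndraw=1, seed=0)
    return StandardizedGSet(
        traits=traits,
        draws={p: np.asarray(d, float) for p, d in draws_by_pop.items()},
        vabar=vb,
    )


def _const(G, n=30):
    return np.repeat(np.asarray(G, float)[None], n, axis=0)


class TestVectorize:
    def test_identity(self):
        assert np.allclose(vectorize_g(np.eye(3)), [1, 1, 1, 0, 0, 0])

    def test_offdiagonal_scaling(self):
        v = vectorize_g(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert np.allclose(v, [1.0, 1.0, 0.5 * np.sqrt(2)])

    def test_inner_product_matches_frobenius(self, rng):
        for _ in range(10):
            A = random_psd(rng, 4)
            B = random_psd(rng, 4)
            assert np.dot(vectorize_g(A), vectorize_g(B)) == pytest.approx(
                np.sum(A * B), rel=1e-12
            )

    def test_roundtrip(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 6))
            A = random_psd(rng, n)
            assert np.allclose(devectorize_g(vectorize_g(A), n), A, atol=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            vectorize_g(np.array([[1.0, 0.2], [0.1, 1.0]]))


class TestBuildTensor:
    def test_identical_populations_zero_tensor(self):
        gs = _gset({p: _const(np.eye(3)) for p in "abcd"})
        d = build_tensor(gs)
        assert np.allclose(d.S, 0.0, atol=1e-12)
        assert np.allclose(d.alphas, 0.0, atol=1e-12)

    def test_two_population_closed_form(self, rng):
        G1 = random_psd(rng, 3)
        G2 = random_psd(rng, 3)
        d = build_tensor(_gset({"a": _const(G1), "b": _const(G2)}))
        v1, v2 = vectorize_g(G1), vectorize_g(G2)
        expected = np.linalg.norm(v1 - v2) ** 2 / 2
        assert d.alphas[0] == pytest.approx(expected, rel=1e-10)
        assert np.allclose(d.alphas[1:], 0.0, atol=1e-10)
        E1 = d.eigentensors[0]
        diff = devectorize_g((v1 - v2) / np.linalg.norm(v1 - v2), 3)
        assert min(
            np.max(np.abs(E1 - diff)), np.max(np.abs(E1 + diff))
        ) < 1e-10

    def test_spectral_identities(self, rng):
        gs = _gset({f"p{k}": _const(random_psd(rng, 3)) for k in range(4)})
        d = build_tensor(gs)
        assert d.alphas.sum() == pytest.approx(np.trace(d.S), abs=1e-10)
        q = len(d.alphas)
        for i in range(q):
            for j in range(q):
                ip = np.sum(d.eigentensors[i] * d.eigentensors[j])
                assert ip == pytest.approx(1.0 if i == j else 0.0, abs=1e-10)

    def test_brute_force_oracle(self, rng):
        from .oracles import brute_force_tensor

        Gs = [random_psd(rng, 3) for _ in range(4)]
        gs = _gset({f"p{k}": _const(G) for k, G in enumerate(Gs)})
        d = build_tensor(gs)
        S_bf, w_bf, tensors_bf = brute_force_tensor(Gs)
        assert np.allclose(d.S, S_bf, atol=1e-10)
        assert np.allclose(d.alphas, np.maximum(w_bf, 0), atol=1e-10)
        for k in range(3):  # eigentensors up to sign
            err = min(
                np.max(np.abs(d.eigentensors[k] - tensors_bf[k])),
                np.max(np.abs(d.eigentensors[k] + tensors_bf[k])),
            )
            assert err < 1e-8

    def test_scale_equivariance(self, rng):
        Gs = {f"p{k}": _const(random_psd(rng, 3)) for k in range(4)}
        d1 = build_tensor(_gset(Gs))
        c = 2.5
        d2 = build_tensor(_gset({p: c * G for p, G in Gs.items()}))
        assert np.allclose(d2.alphas, c**2 * d1.alphas, rtol=1e-10)

    def test_fewer_than_two_populations(self, rng):
        with pytest.raises(ValueError, match="2 populations"):
            build_tensor(_gset({"a": _const(np.eye(2))}))

    def test_posterior_fraction_contains_point_fraction(self, rng):
        # self-consistent input: constant posteriors -> per-draw fractions
        # equal the point fraction exactly
        gs = _gset({f"p{k}": _const(random_psd(rng, 3)) for k in range(4)})
        d = build_tensor(gs)
        assert np.allclose(d.fraction_draws, d.fraction[None, :], atol=1e-10)


class TestCoordinates:
    def test_eigentensor_basis_coordinates(self, rng):
        gs = _gset({f"p{k}": _const(random_psd(rng, 3)) for k in range(3)})
        d = build_tensor(gs)
        E1 = d.eigentensors[0]
        c = 3.7
        gs2 = _gset({"a": _const(c * E1), "b": _const(np.zeros((3, 3)))})
        co = coordinates(gs2, d)
        assert co.draws[0, 0, 0] == pytest.approx(c, rel=1e-10)
        assert abs(co.draws[0, 0, 1]) < 1e-10
        # an eigentensor has unit coordinate on itself
        gs3 = _gset({"a": _const(E1), "b": _const(np.zeros((3, 3)))})
        co3 = coordinates(gs3, d)
        assert co3.draws[0, 0, 0] == pytest.approx(1.0, rel=1e-10)

    def test_matches_elementwise_sum_oracle(self, rng):
        gs = _gset({f"p{k}": np.stack([random_psd(rng, 3) for _ in range(20)]) for k in range(3)})
        d = build_tensor(gs)
        co = coordinates(gs, d)
        for t in range(20):
            for j, p in enumerate(gs.populations):
                G = gs.draws[p][t]
                brute = sum(
                    G[i1, i2] * d.eigentensors[0][i1, i2]
                    for i1 in range(3)
                    for i2 in range(3)
                )
                assert co.draws[t, j, 0] == pytest.approx(brute, abs=1e-10)

    def test_intervals_table(self, rng):
        gs = _gset({f"p{k}": np.stack([random_psd(rng, 2) for _ in range(30)]) for k in range(3)})
        d = build_tensor(gs)
        co = coordinates(gs, d)
        assert set(co.intervals["level"]) == {0.5, 0.75, 0.95}
        assert (co.intervals["lo"] <= co.intervals["hi"]).all()


class TestEigentensorTraits:
    def test_pure_diagonal_eigentensor(self):
        gs = _gset({"a": _const(np.diag([2.0, 1.0, 1.0])), "b": _const(np.diag([0.5, 1.0, 1.0]))})
        d = build_tensor(gs)
        rep = eigentensor_traits(d, 0)
        lead = rep.iloc[0]
        assert lead["share"] == pytest.approx(1.0, abs=1e-10)
        assert abs(lead["loading_t1"]) == pytest.approx(1.0, abs=1e-10)

    def test_constructed_97_percent_share(self):
        # eigentensor with lambda = (sqrt(.97), sqrt(.03)) in Frobenius norm 1
        lam = np.array([np.sqrt(0.97), np.sqrt(0.03)])
        E = np.diag(lam)
        d = build_tensor(_gset({"a": _const(np.eye(2)), "b": _const(2 * np.eye(2))}))
        d.eigentensors = np.array([E])
        rep = eigentensor_traits(d, 0)
        assert rep["share"].iloc[0] == pytest.approx(0.97, abs=1e-12)

    def test_shares_sum_to_one(self, rng):
        for _ in range(10):
            gs = _gset({f"p{k}": _const(random_psd(rng, 3)) for k in range(4)})
            d = build_tensor(gs)
            for i in range(len(d.eigentensors)):
                rep = eigentensor_traits(d, i)
                if np.sum(np.abs(d.eigentensors[i])) > 1e-12:
                    assert rep["share"].sum() == pytest.approx(1.0, abs=1e-8)


class TestDistances:
    def _coords(self, xy):
        from wildg.tensor import CoordinateTable
        import pandas as pd

        xy = np.asarray(xy, float)
        draws = xy[None, :, :]
        return CoordinateTable(
            populations=[f"p{k}" for k in range(len(xy))],
            draws=draws,
            mode=xy,
            intervals=pd.DataFrame(),
        )

    def test_3_4_5(self):
        dset = tensor_distances(self._coords([[0.0, 0.0], [3.0, 4.0]]), k=2)
        assert dset.mode[0, 1] == pytest.approx(5.0)

    def test_identical_zero(self):
        dset = tensor_distances(self._coords([[1.0, 2.0], [1.0, 2.0]]), k=2)
        assert dset.mode[0, 1] == 0.0

    def test_rotation_invariance(self, rng):
        xy = rng.standard_normal((5, 2))
        th = 0.7
        Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d1 = tensor_distances(self._coords(xy), k=2).mode
        d2 = tensor_distances(self._coords(xy @ Rm.T), k=2).mode
        assert np.allclose(d1, d2, atol=1e-12)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            tensor_distances(self._coords([[0.0, 0.0], [1.0, 1.0]]), k=3)


class TestNullPvalues:
    def _sets(self, rng, m=3, n_sets=20, spread=1.0):
        out = []
        for _ in range(n_sets):
            out.append(_gset({f"p{k}": _const(random_psd(rng, 3, scale=spread)) for k in range(m)}))
        return out

    def test_identical_nulls_give_p_one(self, rng):
        gs = _gset({f"p{k}": _const(random_psd(rng, 3)) for k in range(3)})
        d = build_tensor(gs)
        p = tensor_null_pvalues(d, [gs] * 20)
        assert p["p_value"].iloc[0] == 1.0

    def test_dominant_observed_gives_p_zero_reported_floor(self, rng):
        strong = _gset(
            {
                "a": _const(np.diag([10.0, 1.0, 1.0])),
                "b": _const(np.diag([1.0, 1.0, 1.0])),
                "c": _const(np.diag([1.00001, 1.0, 1.0])),
            }
        )
        d = build_tensor(strong)
        nulls = []
        for k in range(25):
            base = random_psd(rng, 3)
            nulls.append(
                _gset({p: _const(base + 0.3 * random_psd(rng, 3)) for p in "abc"})
            )
        rep = tensor_null_pvalues(d, nulls)
        assert rep["p_value"].iloc[0] == 0.0
        assert rep["p_reported"].iloc[0] == pytest.approx(1 / 25)

    def test_too_few_nulls(self, rng):
        gs = _gset({f"p{k}": _const(random_psd(rng, 3)) for k in range(3)})
        d = build_tensor(gs)
        with pytest.raises(ValueError, match="20"):
            tensor_null_pvalues(d, [gs] * 5)
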