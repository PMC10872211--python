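import numpy as np
import pandas as pd
import pytest

from wildg.animal_model import MCMCSettings, ModelSpec, PosteriorSamples, build_design
from wildg.nullmodel import (
    NullConfig,
    founder_bv_tables,
    propagate_null_bv,
    recompose_phenotypes,
    run_null,
    shuffle_founder_bv,
)
from wildg.pedigree import from_frame, inbreeding

TRAITS = ["t1", "t2"]


def _founder_table(pop, n, rng):
    df = pd.DataFrame(rng.standard_normal((n, 2)), columns=TRAITS)
    df.insert(0, "id", [f"{pop}{k}" for k in range(n)])
    return df


class TestShuffle:
    def test_pooled_multiset_preserved(self, rng):
        tabs = {p: _founder_table(p, 10 + i, rng) for i, p in enumerate("abc")}
        out = shuffle_founder_bv(tabs, seed=1)
        pooled_in = np.sort(np.concatenate([t[TRAITS].to_numpy() for t in tabs.values()]), axis=0)
        pooled_out = np.sort(np.concatenate([t[TRAITS].to_numpy() for t in out.values()]), axis=0)
        assert np.array_equal(pooled_in, pooled_out)
        for p in tabs:
            assert list(out[p]["id"]) == list(tabs[p]["id"])

    def test_same_seed_same_permutation(self, rng):
        tabs = {p: _founder_table(p, 8, rng) for p in "ab"}
        o1 = shuffle_founder_bv(tabs, seed=9)
        o2 = shuffle_founder_bv(tabs, seed=9)
        for p in tabs:
            pd.testing.assert_frame_equal(o1[p], o2[p])

    def test_single_population_within_permutation(self, rng):
        tabs = {"a": _founder_table("a", 12, rng)}
        out = shuffle_founder_bv(tabs, seed=2)
        assert sorted(map(tuple, out["a"][TRAITS].to_numpy())) == sorted(
            map(tuple, tabs["a"][TRAITS].to_numpy())
        )


def _sib_pedigree(n_founders, n_kids):
    rows = [(f"f{k}", "NA", "NA", 1) for k in range(n_founders)]
    rows += [(f"o{k}", "f0", "f1", 2) for k in range(n_kids)]
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "cohort"])
    df["population"] = "x"
    return from_frame(df)


class TestPropagate:
    def test_zero_founders_zero_everywhere(self):
        ped = _sib_pedigree(20, 50)
        fb = pd.DataFrame(np.zeros((20, 2)), columns=TRAITS)
        fb.insert(0, "id", [f"f{k}" for k in range(20)])
        bv = propagate_null_bv(ped, fb, inbreeding(ped), seed=1)
        assert np.allclose(bv[TRAITS].to_numpy(), 0.0)

    def test_segregation_covariance_non_inbred(self, rng):
        ped = _sib_pedigree(300, 10_000)
        fb = _founder_table("f", 300, rng)
        fb["id"] = [f"f{k}" for k in range(300)]
        bv = propagate_null_bv(ped, fb, inbreeding(ped), seed=2)
        vals = bv.set_index("id")
        Grand = np.cov(fb[TRAITS].to_numpy(), rowvar=False)
        mid = 0.5 * (vals.loc["f0"].to_numpy() + vals.loc["f1"].to_numpy())
        kids = vals.loc[[f"o{k}" for k in range(10_000)]].to_numpy()
        C = np.cov(kids - mid, rowvar=False)
        assert np.max(np.abs(C - Grand / 2) / np.abs(Grand / 2).max()) < 0.05

    def test_inbred_parents_quarter_variance(self, rng):
        ped = _sib_pedigree(300, 10_000)
        fb = _founder_table("f", 300, rng)
        fb["id"] = [f"f{k}" for k in range(300)]
        F = np.full(ped.n, 0.5)  # pretend both parents have F = 0.5
        bv = propagate_null_bv(ped, fb, F, seed=3)
        vals = bv.set_index("id")
        Grand = np.cov(fb[TRAITS].to_numpy(), rowvar=False)
        mid = 0.5 * (vals.loc["f0"].to_numpy() + vals.loc["f1"].to_numpy())
        kids = vals.loc[[f"o{k}" for k in range(10_000)]].to_numpy()
        C = np.cov(kids - mid, rowvar=False)
        assert np.max(np.abs(C - Grand / 4) / np.abs(Grand / 4).max()) < 0.05

    def test_missing_founder_rejected(self, rng):
        ped = _sib_pedigree(5, 3)
        fb = _founder_table("f", 3, rng)
        with pytest.raises(ValueError, match="missing"):
            propagate_null_bv(ped, fb, inbreeding(ped), seed=4)


def _fake_fit(n_draws, P, T, G=None, PE=None, Y=None, R=None, B=None, nyr=1):
    z = np.zeros((n_draws, T, T))

    def rep(M):
        return np.repeat(np.asarray(M, float)[None], n_draws, axis=0)

    return PosteriorSamples(
        traits=TRAITS,
        G=rep(G) if G is not None else z.copy(),
        PE=rep(PE) if PE is not None else z.copy(),
        Y=rep(Y) if Y is not None else z.copy(),
        R=rep(R) if R is not None else z.copy(),
        obs_var=np.zeros((n_draws, T)),
        B=rep(B) if B is not None else np.zeros((n_draws, P, T)),
        fixed_names=["intercept", "age", "age2"],
        phen_var=np.ones(T),
        settings=MCMCSettings(burnin=1, iterations=10, thin=1),
    )


def _design(n, rng):
    df = pd.DataFrame(
        {
            "id": [f"i{k % (n // 2)}" for k in range(n)],
            "year": 2000 + np.arange(n) % 50,
            "age": rng.integers(1, 4, n).astype(float),
            "t1": rng.standard_normal(n),
            "t2": rng.standard_normal(n),
        }
    )
    spec = ModelSpec(traits=TRAITS)
    return build_design(df, spec), df


class TestRecompose:
    def test_zero_everything_gives_fixed_part(self, rng):
        design, df = _design(40, rng)
        B = rng.standard_normal((design.X.shape[1], 2))
        fit = _fake_fit(5, design.X.shape[1], 2, B=B)
        bv = pd.DataFrame(np.zeros((len(set(design.ids)), 2)), columns=TRAITS)
        bv.insert(0, "id", sorted(set(design.ids)))
        out = recompose_phenotypes(bv, fit, draw=0, design=design, seed=1)
        assert np.allclose(out[TRAITS].to_numpy(), design.X @ B, atol=1e-12)

    def test_deterministic_under_draw_and_seed(self, rng):
        design, df = _design(40, rng)
        fit = _fake_fit(5, design.X.shape[1], 2, G=np.eye(2), R=0.5 * np.eye(2))
        bv = pd.DataFrame(rng.standard_normal((len(set(design.ids)), 2)), columns=TRAITS)
        bv.insert(0, "id", sorted(set(design.ids)))
        o1 = recompose_phenotypes(bv, fit, 2, design, seed=9)
        o2 = recompose_phenotypes(bv, fit, 2, design, seed=9)
        pd.testing.assert_frame_equal(o1, o2)

    def test_component_addition(self, rng):
        # phenotypic covariance ~ Gsim + PE + Y + R over many records
        design, df = _design(5000, rng)
        PE = np.diag([0.3, 0.2])
        Yc = np.diag([0.15, 0.25])
        R = np.diag([0.5, 0.4])
        fit = _fake_fit(3, design.X.shape[1], 2, PE=PE, Y=Yc, R=R)
        uniq = sorted(set(design.ids))
        Gsim = np.array([[0.4, 0.1], [0.1, 0.3]])
        bvv = rng.multivariate_normal(np.zeros(2), Gsim, size=len(uniq))
        bv = pd.DataFrame(bvv, columns=TRAITS)
        bv.insert(0, "id", uniq)
        out = recompose_phenotypes(bv, fit, 0, design, seed=3)
        C = np.cov(out[TRAITS].to_numpy(), rowvar=False)
        expected = Gsim + PE + Yc + R
        assert np.max(np.abs(np.diag(C) - np.diag(expected)) / np.diag(expected)) < 0.1


class TestRunNull:
    def test_collection_size_and_reproducibility(self):
        from wildg.pedigree import ainverse
        from wildg.simulate import (
            StudyConfig,
            default_life_history,
            simulate_breeding_values,
            simulate_pedigree,
            simulate_phenotypes,
        )
        from wildg.animal_model import fit_animal_model

        arch = default_life_history()
        spec = ModelSpec(traits=arch.traits)
        fits, peds, designs, ainvs, Fs = {}, {}, {}, {}, {}
        for i, pop in enumerate(["a", "b"]):
            cfg = StudyConfig(n_populations=1, n_founders=30, n_years=5, seed=i)
            ped = simulate_pedigree(cfg, pop, 10 + i)
            F = inbreeding(ped)
            bv = simulate_breeding_values(ped, arch.G, F, 20 + i, traits=arch.traits)
            phen = simulate_phenotypes(ped, bv, arch, 30 + i)
            design = build_design(phen, spec)
            Ai = ainverse(ped, F)
            fits[pop] = fit_animal_model(
                design, Ai, spec, MCMCSettings(burnin=100, iterations=500, thin=10, seed=i), ped.ids
            )
            peds[pop], designs[pop], ainvs[pop], Fs[pop] = ped, design, Ai, F
        cfg = NullConfig(
            n_replicates=2,
            posterior_subsample=20,
            mcmc=MCMCSettings(burnin=100, iterations=400, thin=10),
            seed=5,
        )
        coll = run_null(fits, peds, designs, ainvs, Fs, spec, cfg)
        assert coll.n_replicates == 2
        for rep in coll.replicates:
            assert set(rep) == {"a", "b"}
            assert rep["a"].shape == (20, 3, 3)
        coll2 = run_null(fits, peds, designs, ainvs, Fs, spec, cfg)
        assert np.array_equal(coll.replicates[0]["a"], coll2.replicates[0]["a"])
        mg = coll.mean_null_g()
        assert mg["a"].shape == (3, 3)
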