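import numpy as np
import pandas as pd
import pytest

from wildg.animal_model import (
    MCMCSettings,
    ModelSpec,
    PosteriorSamples,
    build_design,
    convergence_diagnostics,
    fit_animal_model,
    prior_scale,
)
from wildg.pedigree import ainverse, from_frame, inbreeding
from wildg.simulate import (
    StudyConfig,
    default_life_history,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
)

SPEC = ModelSpec(traits=["laying_date", "clutch_size", "fledging_success"])


def _phen(n=40, missing_age=False):
    df = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n)],
            "year": 2000 + np.arange(n) % 5,
            "age": 1.0 + np.arange(n) % 3,
            "sex": ["F"] * n,
            "observer": ["o1"] * n,
            "date": 100.0 + np.arange(n) % 7,
            "laying_date": np.random.default_rng(1).normal(100, 5, n),
            "clutch_size": np.random.default_rng(2).normal(9, 1, n),
            "fledging_success": np.random.default_rng(3).normal(6, 1, n),
        }
    )
    if missing_age:
        df.loc[0, "age"] = np.nan
    return df


class TestBuildDesign:
    def test_average_data_augmentation_fills_column_mean(self):
        df = _phen(missing_age=True)
        d = build_design(df, SPEC)
        assert d.n_records == len(df)
        # centered age of the augmented record is 0 (it sits at the mean)
        assert d.X[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_deletion_mode_drops_record(self):
        df = _phen(missing_age=True)
        spec = ModelSpec(traits=SPEC.traits, missing_covariates="delete")
        d = build_design(df, spec)
        assert d.n_records == len(df) - 1

    def test_quadratic_age_columns(self):
        d = build_design(_phen(), SPEC)
        assert d.fixed_names[:3] == ["intercept", "age", "age2"]
        age = d.X[:, 1]
        assert age.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(d.X[:, 2], age**2)

    def test_age_class_factor(self):
        spec = ModelSpec(traits=SPEC.traits, age_mode="classes")
        d = build_design(_phen(), spec)
        assert any(n.startswith("age[") for n in d.fixed_names)

    def test_missing_categorical_drops_record(self):
        df = _phen()
        df.loc[0, "year"] = np.nan
        with pytest.warns(UserWarning, match="categorical"):
            d = build_design(df, SPEC)
        assert d.n_records == len(df) - 1


def test_prior_scale_rule():
    # 3 traits, 4 random factors, phenotypic variances (2, 4, 6)
    V = prior_scale([2.0, 4.0, 6.0], 4)
    assert np.allclose(V, np.diag([0.5, 1.0, 1.5]))
    spec = ModelSpec(traits=["a", "b", "c"])  # G + PE + Y + R
    assert spec.n_random_factors == 4


class TestDiagnostics:
    def _fake_post(self, series):
        n = len(series)
        G = np.zeros((n, 3, 3))
        for i in range(3):
            for j in range(3):
                G[:, i, j] = series
        z = np.zeros((n, 3, 3))
        return PosteriorSamples(
            traits=["a", "b", "c"],
            G=G,
            PE=z.copy(),
            Y=z.copy(),
            R=z.copy(),
            obs_var=np.zeros((n, 3)),
            B=np.zeros((n, 1, 3)),
            fixed_names=["intercept"],
            phen_var=np.ones(3),
            settings=MCMCSettings(),
        )

    def test_independent_chain_passes(self):
        rng = np.random.default_rng(0)
        rep = convergence_diagnostics(self._fake_post(rng.standard_normal(2000)))
        assert rep.attrs["passed"]
        g = rep[rep.component == "G"]
        assert (g["lag1_autocorr"].abs() < 0.1).all()

    def test_ar1_chain_fails(self):
        rng = np.random.default_rng(1)
        x = np.zeros(2000)
        for t in range(1, 2000):
            x[t] = 0.9 * x[t - 1] + rng.standard_normal()
        rep = convergence_diagnostics(self._fake_post(x))
        assert not rep.attrs["passed"]

    def test_every_covariance_element_listed_once(self):
        rep = convergence_diagnostics(self._fake_post(np.random.default_rng(2).standard_normal(200)))
        counts = rep.groupby(["component", "parameter"]).size()
        assert (counts == 1).all()
        # 6 unique elements per 3x3 component x 4 components + 3 obs variances
        assert len(rep) == 4 * 6 + 3

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            convergence_diagnostics(self._fake_post(np.zeros(50)))


@pytest.fixture(scope="module")
def fitted():
    """One small fitted model shared across sampler tests."""
    cfg = StudyConfig(n_populations=1, n_founders=60, n_years=10, seed=5)
    ped = simulate_pedigree(cfg, "p1", 11)
    arch = default_life_history()
    F = inbreeding(ped)
    bv = simulate_breeding_values(ped, arch.G, F, 12, traits=arch.traits)
    phen = simulate_phenotypes(ped, bv, arch, 13)
    spec = ModelSpec(traits=arch.traits)
    design = build_design(phen, spec)
    Ai = ainverse(ped, F)
    settings = MCMCSettings(burnin=500, iterations=4000, thin=10, seed=21)
    post = fit_animal_model(design, Ai, spec, settings, ped.ids)
    return dict(ped=ped, arch=arch, design=design, Ai=Ai, spec=spec, post=post, phen=phen)


class TestSampler:
    def test_retained_draw_count(self, fitted):
        assert fitted["post"].n_draws == 400

    def test_all_covariance_draws_psd(self, fitted):
        for comp in ("G", "PE", "Y", "R"):
            M = fitted["post"].component(comp)
            w = np.linalg.eigvalsh(M)
            assert w.min() > 0

    def test_deterministic_under_seed(self, fitted):
        settings = MCMCSettings(burnin=100, iterations=500, thin=10, seed=77)
        p1 = fit_animal_model(fitted["design"], fitted["Ai"], fitted["spec"], settings, fitted["ped"].ids)
        p2 = fit_animal_model(fitted["design"], fitted["Ai"], fitted["spec"], settings, fitted["ped"].ids)
        assert np.array_equal(p1.G, p2.G)

    def test_posterior_variances_are_sane(self, fitted):
        # total variance roughly matches the phenotypic variance
        post = fitted["post"]
        total = (post.G + post.PE + post.Y + post.R).mean(axis=0)
        assert np.all(np.diag(total) < 3 * post.phen_var)
        assert np.all(np.diag(total) > post.phen_var / 3)

    def test_missing_trait_values_imputed(self, fitted):
        design = fitted["design"]
        Y2 = design.Y.copy()
        rng = np.random.default_rng(3)
        mask = rng.random(Y2.shape) < 0.1
        Y2[mask] = np.nan
        from dataclasses import replace

        d2 = replace(design, Y=Y2)
        settings = MCMCSettings(burnin=200, iterations=1000, thin=10, seed=5)
        post = fit_animal_model(d2, fitted["Ai"], fitted["spec"], settings, fitted["ped"].ids)
        assert np.all(np.isfinite(post.G))

    def test_thinning_halves_draws_same_posterior(self, fitted):
        base = MCMCSettings(burnin=500, iterations=6000, thin=10, seed=31)
        double = MCMCSettings(burnin=500, iterations=6000, thin=20, seed=32)
        p1 = fit_animal_model(fitted["design"], fitted["Ai"], fitted["spec"], base, fitted["ped"].ids)
        p2 = fit_animal_model(fitted["design"], fitted["Ai"], fitted["spec"], double, fitted["ped"].ids)
        assert p2.n_draws * 2 == p1.n_draws
        for i in range(3):
            lo1, hi1 = np.quantile(p1.G[:, i, i], [0.025, 0.975])
            lo2, hi2 = np.quantile(p2.G[:, i, i], [0.025, 0.975])
            assert max(lo1, lo2) < min(hi1, hi2)  # overlapping 95% intervals

    def test_identifiability_error(self, fitted):
        from dataclasses import replace

        d = fitted["design"]
        d2 = replace(d, Y=d.Y[:2], X=d.X[:2], ids=d.ids[:2],
                     year_codes=d.year_codes[:2], obs_codes=d.obs_codes[:2])
        with pytest.raises(ValueError, match="identifiab"):
            fit_animal_model(d2, fitted["Ai"], fitted["spec"],
                             MCMCSettings(burnin=10, iterations=20, thin=2), fitted["ped"].ids)

    def test_hdf5_roundtrip(self, fitted, tmp_path):
        p = tmp_path / "post.h5"
        fitted["post"].save(p)
        back = PosteriorSamples.load(p)
        assert np.array_equal(back.G, fitted["post"].G)
        assert back.traits == fitted["post"].traits
        assert back.settings.thin == fitted["post"].settings.thin


def test_saturated_variance_split_limit():
    """Founders only, one record each, no PE/Y: G + R posterior mean
    approximates the sample phenotypic covariance."""
    n = 2000
    rng = np.random.default_rng(8)
    P = np.array([[1.0, 0.3, 0.1], [0.3, 1.2, 0.2], [0.1, 0.2, 0.8]])
    Yv = rng.multivariate_normal(np.zeros(3), P, size=n)
    df = pd.DataFrame(
        {
            "id": [f"f{k}" for k in range(n)],
            "sire": "NA",
            "dam": "NA",
            "cohort": 1,
            "population": "x",
        }
    )
    ped = from_frame(df)
    phen = pd.DataFrame(Yv, columns=["t1", "t2", "t3"])
    phen.insert(0, "id", ped.ids)
    phen["age"] = rng.integers(1, 5, size=n).astype(float)
    spec = ModelSpec(traits=["t1", "t2", "t3"], use_pe=False, use_year=False)
    design = build_design(phen, spec)
    Ai = ainverse(ped)
    post = fit_animal_model(
        design, Ai, spec, MCMCSettings(burnin=500, iterations=3000, thin=10, seed=9), ped.ids
    )
    total = (post.G + post.R).mean(axis=0)
    S = np.cov(Yv, rowvar=False)
    assert np.all(np.abs(np.diag(total) - np.diag(S)) / np.diag(S) < 0.15)
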