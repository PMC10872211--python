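import numpy as np
import pandas as pd
import pytest

from wildg.niche import CLIMATE_VARS
from wildg.pedigree import from_frame, inbreeding
from wildg.simulate import (
    StudyConfig,
    default_life_history,
    default_morphology,
    simulate_breeding_values,
    simulate_climate_grid,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)


def _founder_frame(n):
    df = pd.DataFrame(
        {
            "id": [f"f{k}" for k in range(n)],
            "sire": "NA",
            "dam": "NA",
            "cohort": 1,
            "population": "x",
        }
    )
    return from_frame(df)


class TestPedigreeSim:
    def test_single_year_all_founders(self):
        cfg = StudyConfig(n_founders=50, n_years=1, immigration_rate=0.0)
        ped = simulate_pedigree(cfg, "p", 1)
        assert ped.founders().all()
        assert set(ped.cohort) == {1}

    def test_deterministic_under_seed(self):
        cfg = StudyConfig(n_founders=60, n_years=8)
        p1 = simulate_pedigree(cfg, "p", 9)
        p2 = simulate_pedigree(cfg, "p", 9)
        assert p1.ids == p2.ids
        assert np.array_equal(p1.sire, p2.sire)
        assert np.array_equal(p1.dam, p2.dam)

    def test_default_config_founder_fraction_band(self):
        cfg = StudyConfig()  # 200 founders, 25 years
        ped = simulate_pedigree(cfg, "p", 3)
        frac = ped.founders().mean()
        assert 0.1 < frac < 0.9

    def test_immigrant_founders_enter_multiple_cohorts(self):
        cfg = StudyConfig(n_founders=80, n_years=15, immigration_rate=0.1)
        ped = simulate_pedigree(cfg, "p", 4)
        cohorts = set(ped.cohort[ped.founders()])
        assert len(cohorts) > 3


class TestBreedingValues:
    def test_zero_g_gives_zero_bv(self):
        ped = _founder_frame(20)
        bv = simulate_breeding_values(ped, np.zeros((2, 2)), inbreeding(ped), 1)
        assert (bv.iloc[:, 1:].to_numpy() == 0).all()

    def test_founder_covariance_matches_g(self):
        ped = _founder_frame(10_000)
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        bv = simulate_breeding_values(ped, G, np.zeros(ped.n), 2)
        C = np.cov(bv.iloc[:, 1:].to_numpy(), rowvar=False)
        assert np.max(np.abs(C - G)) < 0.05

    def test_offspring_segregation_variance(self):
        # 10,000 replicate offspring of one non-inbred pair: deviations
        # around the parental mean have covariance G/2
        rows = [("s", "NA", "NA", 1), ("d", "NA", "NA", 1)] + [
            (f"o{k}", "s", "d", 2) for k in range(10_000)
        ]
        df = pd.DataFrame(rows, columns=["id", "sire", "dam", "cohort"])
        df["population"] = "x"
        ped = from_frame(df)
        G = np.array([[1.0, 0.3], [0.3, 0.8]])
        bv = simulate_breeding_values(ped, G, inbreeding(ped), 3)
        vals = bv.set_index("id")
        parents = 0.5 * (vals.loc["s"].to_numpy() + vals.loc["d"].to_numpy())
        kids = vals.drop(index=["s", "d"]).to_numpy()
        C = np.cov(kids - parents, rowvar=False)
        assert np.max(np.abs(C - G / 2)) < 0.05

    def test_non_psd_g_rejected(self):
        ped = _founder_frame(5)
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_breeding_values(ped, np.array([[1.0, 2.0], [2.0, 1.0]]), np.zeros(5), 1)


class TestPhenotypes:
    def test_all_zero_components_give_zero_phenotypes(self):
        cfg = StudyConfig(n_founders=40, n_years=6)
        ped = simulate_pedigree(cfg, "p", 5)
        arch = default_morphology()
        Z = np.zeros((3, 3))
        arch2 = type(arch)(
            traits=arch.traits, G=Z, PE=Z, Y=Z, R=Z, obs_var=np.zeros(3), group="morphology"
        )
        bv = simulate_breeding_values(ped, Z, inbreeding(ped), 1, traits=arch.traits)
        phen = simulate_phenotypes(ped, bv, arch2, 2)
        assert np.allclose(phen[arch.traits].to_numpy(), 0.0)

    def test_permanent_environment_shared_within_individual(self):
        cfg = StudyConfig(n_founders=60, n_years=10)
        ped = simulate_pedigree(cfg, "p", 6)
        arch = default_morphology()
        # isolate PE: all other components zero, no fixed effects
        Z = np.zeros((3, 3))
        arch2 = type(arch)(
            traits=arch.traits,
            G=Z,
            PE=np.eye(3),
            Y=Z,
            R=Z,
            obs_var=np.zeros(3),
            group="morphology",
        )
        bv = simulate_breeding_values(ped, Z, inbreeding(ped), 1, traits=arch.traits)
        phen = simulate_phenotypes(ped, bv, arch2, 3)
        reps = phen.groupby("id")[arch.traits].nunique()
        multi = phen["id"].value_counts()
        multi = multi[multi > 1].index
        assert (reps.loc[multi] == 1).all().all()

    def test_variance_addition(self):
        cfg = StudyConfig(n_founders=600, n_years=12)
        ped = simulate_pedigree(cfg, "p", 7)
        arch = default_life_history()
        arch2 = type(arch)(
            traits=arch.traits,
            G=arch.G,
            PE=arch.PE,
            Y=arch.Y,
            R=arch.R,
            group="life_history",
        )  # fixed effects default to zero
        bv = simulate_breeding_values(ped, arch.G, inbreeding(ped), 8, traits=arch.traits)
        phen = simulate_phenotypes(ped, bv, arch2, 9)
        assert len(phen) > 2000
        total_expected = np.diag(arch.G + arch.PE + arch.Y + arch.R)
        obs = phen[arch.traits].to_numpy().var(axis=0, ddof=1)
        assert np.all(np.abs(obs - total_expected) / total_expected < 0.25)

    def test_life_history_on_females_once_per_year(self):
        cfg = StudyConfig(n_founders=60, n_years=10)
        ped = simulate_pedigree(cfg, "p", 10)
        arch = default_life_history()
        bv = simulate_breeding_values(ped, arch.G, inbreeding(ped), 1, traits=arch.traits)
        phen = simulate_phenotypes(ped, bv, arch, 2)
        assert set(phen["sex"]) == {"F"}
        assert phen.groupby(["id", "year"]).size().max() == 1


class TestClimate:
    def test_zero_correlation_length_gives_uncorrelated_neighbours(self):
        cfg = StudyConfig(grid_shape=(40, 40), climate_corr_cells=0.0)
        grid = simulate_climate_grid(cfg, 1)
        v = grid.cells["t_annual_mean"].to_numpy().reshape(40, 40)
        # remove the deterministic latitudinal trend by differencing rows
        resid = v - v.mean(axis=1, keepdims=True)
        r = np.corrcoef(resid[:, :-1].ravel(), resid[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_same_seed_identical(self):
        cfg = StudyConfig()
        g1 = simulate_climate_grid(cfg, 11)
        g2 = simulate_climate_grid(cfg, 11)
        pd.testing.assert_frame_equal(g1.cells, g2.cells)

    def test_dominant_first_axis(self):
        from wildg.niche import fit_niche_pca

        cfg = StudyConfig()
        grid = simulate_climate_grid(cfg, 12)
        space = fit_niche_pca(grid)
        assert space.explained_fraction[0] > 0.4

    def test_too_few_masked_cells(self):
        cfg = StudyConfig(grid_shape=(2, 2), n_populations=10)
        with pytest.raises(ValueError, match="masked"):
            simulate_climate_grid(cfg, 1)


class TestStudy:
    @pytest.fixture(scope="class")
    def small_cfg(self):
        return dict(
            n_populations=3, n_founders=30, n_years=6, groups=("life_history",)
        )

    def test_delta_zero_shares_one_true_g(self, small_cfg):
        study = simulate_study(StudyConfig(delta=0.0, seed=1, **small_cfg))
        Gs = [study.true_G[(p, "life_history")] for p in study.pedigrees]
        for G in Gs[1:]:
            assert np.allclose(G, Gs[0])

    def test_delta_increases_true_g_divergence(self, small_cfg):
        s0 = simulate_study(StudyConfig(delta=0.0, seed=2, **small_cfg))
        s1 = simulate_study(StudyConfig(delta=1.5, seed=2, **small_cfg))

        def pairwise(study):
            Gs = [study.true_G[(p, "life_history")] for p in study.pedigrees]
            return sum(
                np.linalg.norm(Gs[i] - Gs[j])
                for i in range(len(Gs))
                for j in range(i + 1, len(Gs))
            )

        assert pairwise(s1) > pairwise(s0)

    def test_referential_integrity(self):
        study = simulate_study(
            StudyConfig(n_populations=5, n_founders=25, n_years=5, seed=3)
        )
        for (pop, group), phen in study.phenotypes.items():
            ids = set(study.pedigrees[pop].ids)
            assert set(phen["id"]).issubset(ids)
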