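import numpy as np
import pytest
from scipy.special import expit

from svdlmm import (
    ScenarioSpec,
    TraitParams,
    additive_matrix,
    family_offsets,
    kinship,
    make_pedigree,
    simulate_binary,
    simulate_gaussian,
)
from svdlmm.simulate import simulate_dataset


class TestScenarioPedigrees:
    @pytest.mark.parametrize(
        "scenario,total,per_family",
        [
            ("nuclear", 400, {4}),
            ("two_trios", 600, {6}),
            ("asymmetric", 1500, {15}),
            ("combination", 1400, {4, 10}),
        ],
    )
    def test_sampled_counts(self, scenario, total, per_family):
        ped = make_pedigree(ScenarioSpec(scenario, n_fam=100))
        off = family_offsets(ped)
        assert off.n == total
        assert set(off.sizes().tolist()) == per_family

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ScenarioSpec("trios", n_fam=1)

    def test_asymmetric_has_three_degrees_of_kinship(self):
        ped = make_pedigree(ScenarioSpec("asymmetric", n_fam=1))
        K = kinship(ped).to_frame()
        assert K.loc["F1_s1", "F1_a1"] == 0.25  # parent-offspring, 1st degree
        assert K.loc["F1_s1", "F1_b1"] == 0.125  # avuncular, 2nd degree
        assert K.loc["F1_a1", "F1_b1"] == 0.0625  # first cousins, 3rd degree

    def test_phantoms_absent_from_sampled_output(self):
        ped = make_pedigree(ScenarioSpec("two_trios", n_fam=2))
        assert all("gp" not in iid for iid in ped.sampled_ids)
        assert len(ped) == 16  # 12 sampled + 4 phantom grandparents


class TestGaussianSimulator:
    def test_zero_genetic_variance_gives_independent_sibs(self):
        ped = make_pedigree(ScenarioSpec("nuclear", n_fam=1))
        par = TraitParams(sigma_g2=0.0, sigma_e2=1.0, seed=0)
        rng = np.random.default_rng(0)
        ys = np.array([simulate_gaussian(ped, par, rng=rng) for _ in range(8000)])
        sib_cov = np.cov(ys[:, 2], ys[:, 3])[0, 1]
        assert abs(sib_cov) < 3 / np.sqrt(8000)
        assert np.var(ys[:, 0]) == pytest.approx(1.0, rel=0.1)

    def test_sib_covariance_matches_2k_sigma_g2(self):
        """Sample sib-sib covariance approaches 2 k sigma_g^2 = 0.5 * 1."""
        ped = make_pedigree(ScenarioSpec("nuclear", n_fam=1))
        par = TraitParams(sigma_g2=1.0, sigma_e2=1.0, seed=0)
        rng = np.random.default_rng(1)
        n_rep = 10_000
        ys = np.array([simulate_gaussian(ped, par, rng=rng) for _ in range(n_rep)])
        sib_cov = np.cov(ys[:, 2], ys[:, 3])[0, 1]
        # Var of a covariance estimate for bivariate normals: (v1*v2 + c^2)/n
        se = np.sqrt((2.0 * 2.0 + 0.5**2) / n_rep)
        assert abs(sib_cov - 0.5) <= 3 * se

    def test_full_covariance_oracle_small_family(self):
        ped = make_pedigree(ScenarioSpec("two_trios", n_fam=1))
        sg2, se2 = 1.5, 0.8
        par = TraitParams(sigma_g2=sg2, sigma_e2=se2, seed=0)
        rng = np.random.default_rng(2)
        n_rep = 10_000
        ys = np.array([simulate_gaussian(ped, par, rng=rng) for _ in range(n_rep)])
        target = se2 * np.eye(6) + sg2 * additive_matrix(kinship(ped)).values
        emp = np.cov(ys, rowvar=False)
        v = np.diag(target)
        se = np.sqrt((np.outer(v, v) + target**2) / n_rep)
        assert np.all(np.abs(emp - target) <= 3 * se)

    def test_fixed_seed_bit_identical(self):
        ped = make_pedigree(ScenarioSpec("combination", n_fam=3))
        par = TraitParams(sigma_g2=1.0, sigma_e2=1.0, seed=123)
        assert np.array_equal(simulate_gaussian(ped, par), simulate_gaussian(ped, par))

    def test_mean_shift_from_design(self):
        ped = make_pedigree(ScenarioSpec("nuclear", n_fam=50))
        off = family_offsets(ped)
        X = np.ones((off.n, 1))
        par = TraitParams(sigma_g2=0.5, sigma_e2=0.5, beta=(3.0,), seed=5)
        y = simulate_gaussian(ped, par, X=X)
        assert y.mean() == pytest.approx(3.0, abs=0.5)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            TraitParams(sigma_g2=-1.0)


class TestBinarySimulator:
    def test_null_model_prevalence_half(self):
        ped = make_pedigree(ScenarioSpec("nuclear", n_fam=250))
        off = family_offsets(ped)
        X = np.ones((off.n, 1))
        par = TraitParams(sigma_g2=0.0, beta=(0.0,), seed=0)
        y = simulate_binary(ped, par, X)
        assert abs(y.mean() - 0.5) <= 3 * np.sqrt(0.25 / off.n)

    def test_rare_trait_prevalence_matches_inverse_logit(self):
        ped = make_pedigree(ScenarioSpec("nuclear", n_fam=250))
        off = family_offsets(ped)
        X = np.ones((off.n, 1))
        par = TraitParams(sigma_g2=0.0, beta=(-5.0,), seed=0)
        p = expit(-5.0)
        counts = []
        rng = np.random.default_rng(4)
        for _ in range(30):
            counts.append(simulate_binary(ped, par, X, rng=rng).sum())
        n_tot = 30 * off.n
        assert abs(sum(counts) / n_tot - p) <= 3 * np.sqrt(p * (1 - p) / n_tot)

    def test_family_concordance_under_strong_genetics(self):
        """With large sigma_g2, case status clusters within families."""
        ped = make_pedigree(ScenarioSpec("nuclear", n_fam=1000))
        off = family_offsets(ped)
        X = np.ones((off.n, 1))
        par = TraitParams(sigma_g2=2.0, beta=(0.0,), seed=9)
        y = simulate_binary(ped, par, X)
        blocks = y.reshape(-1, 4)
        within = np.mean([np.mean(b[:, None] == b[None, :]) for b in blocks])
        between = np.mean(y[:, None][:200] == y[None, :][:, :200])
        assert within > between + 0.05

    def test_fixed_seed_bit_identical(self):
        ped = make_pedigree(ScenarioSpec("two_trios", n_fam=5))
        off = family_offsets(ped)
        X = np.ones((off.n, 1))
        par = TraitParams(sigma_g2=1.0, beta=(0.0,), seed=7)
        assert np.array_equal(simulate_binary(ped, par, X), simulate_binary(ped, par, X))


def test_simulate_dataset_round_trip():
    ped, df = simulate_dataset(
        ScenarioSpec("two_trios", n_fam=10), TraitParams(seed=3), trait="gaussian"
    )
    assert len(df) == 60
    assert list(df.columns) == ["fid", "iid", "sex", "age", "y"]
    assert df["iid"].tolist() == ped.sampled_ids
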