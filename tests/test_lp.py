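import numpy as np
import pytest
from scipy import stats

import oracles
from fourdn import lp_test, synthetic
from fourdn.errors import ValidationError


def block_sigma(n=30, block=5, within=0.7, between=-0.4):
    idx = np.arange(n)
    lab = (idx // block) % 2 == 0
    S = np.where(np.outer(lab, lab) | np.outer(~lab, ~lab), within, between)
    np.fill_diagonal(S, 1.0)
    return S


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.0
        assert lp_test.fisher_z(C)[0, 1] == 0.0

    def test_half_matches_arctanh(self):
        C = np.eye(2)
        C[0, 1] = C[1, 0] = 0.5
        assert lp_test.fisher_z(C)[0, 1] == pytest.approx(np.arctanh(0.5),
                                                          abs=1e-12)
        assert lp_test.fisher_z(C)[0, 1] == pytest.approx(0.5493061443,
                                                          abs=1e-9)

    def test_odd_function(self, rng):
        C = np.clip(rng.uniform(-0.9, 0.9, size=(5, 5)), -1, 1)
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        assert np.abs(lp_test.fisher_z(C) + lp_test.fisher_z(-C)).max() < 1e-14

    def test_perfect_correlation_clipped_finite(self):
        C = np.ones((2, 2))
        Z = lp_test.fisher_z(C)
        assert np.isfinite(Z).all()


class TestLPStatistics:
    def test_identical_matrices_zero(self, rng):
        Z = rng.normal(size=(6, 6))
        Z = (Z + Z.T) / 2
        S, T, argmax = lp_test.lp_statistics([Z, Z, Z], n_obs=10)
        # deviations from the across-sample mean vanish up to rounding
        assert S.max() < 1e-28 and T < 1e-28

    def test_hand_computed_pair(self):
        # k=2, Z values {0, 1} at one off-diagonal pair, n_obs=7:
        # Zbar=0.5, S = 4*(0.25+0.25) = 2.0
        Z1 = np.zeros((2, 2))
        Z2 = np.zeros((2, 2))
        Z2[0, 1] = Z2[1, 0] = 1.0
        S, T, argmax = lp_test.lp_statistics([Z1, Z2], n_obs=7)
        assert T == pytest.approx(2.0, abs=1e-14)
        assert argmax == (0, 1)

    def test_matches_loop_oracle(self, rng):
        Zs = []
        for _ in range(3):
            Z = rng.normal(size=(8, 8))
            Z = (Z + Z.T) / 2
            np.fill_diagonal(Z, 0.0)
            Zs.append(Z)
        S, T, argmax = lp_test.lp_statistics(Zs, n_obs=20)
        exp = oracles.lp_S_oracle(Zs, 20)
        off = ~np.eye(8, dtype=bool)
        assert np.abs(S - exp)[off].max() < 1e-12
        iu, ju = np.triu_indices(8, k=1)
        assert T == pytest.approx(exp[iu, ju].max(), abs=1e-12)

    def test_location_invariance(self, rng):
        Zs = [rng.normal(size=(5, 5)) for _ in range(3)]
        shift = rng.normal(size=(5, 5))
        S1, _, _ = lp_test.lp_statistics(Zs, n_obs=10)
        S2, _, _ = lp_test.lp_statistics([Z + shift for Z in Zs], n_obs=10)
        assert np.abs(S1 - S2).max() < 1e-10

    def test_n_obs_too_small_rejected(self, rng):
        with pytest.raises(ValidationError, match="n_obs - 3"):
            lp_test.lp_statistics([np.eye(3), np.eye(3)], n_obs=3)


class TestSidakEpsilon:
    def test_n2_collapses_to_one_minus_alpha(self):
        assert lp_test.sidak_epsilon(0.05, 2) == pytest.approx(0.95, abs=1e-15)

    def test_alpha_to_zero_limit(self):
        for n in (2, 5, 50):
            assert lp_test.sidak_epsilon(1e-12, n) == pytest.approx(
                1.0, abs=1e-10)

    def test_power_formula(self):
        assert lp_test.sidak_epsilon(0.05, 10) == pytest.approx(
            0.95 ** (2.0 / 90.0), abs=1e-15)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_alpha(self, alpha):
        with pytest.raises(ValidationError):
            lp_test.sidak_epsilon(alpha, 5)


class TestLPTest:
    def test_identical_inputs_accept_with_p_one(self, rng):
        C = np.corrcoef(rng.normal(size=(6, 30)))
        res = lp_test.lp_test(lp_test.LPInput([C, C, C], n_obs=30))
        assert res.T < 1e-28
        assert res.p_value == 1.0
        assert not res.reject

    def test_single_pair_closed_form(self):
        # k=2, n=2: one coefficient, eps = 1 - alpha, df = 1
        r1, r2, n_obs, alpha = 0.9, -0.5, 20, 0.05
        C1 = np.array([[1, r1], [r1, 1.0]])
        C2 = np.array([[1, r2], [r2, 1.0]])
        res = lp_test.lp_test(lp_test.LPInput([C1, C2], n_obs=n_obs,
                                              alpha=alpha))
        z1, z2 = np.arctanh(r1), np.arctanh(r2)
        zbar = (z1 + z2) / 2
        T = (n_obs - 3) * ((z1 - zbar) ** 2 + (z2 - zbar) ** 2)
        crit = stats.chi2.ppf(1 - alpha, df=1)
        assert res.T == pytest.approx(T, abs=1e-12)
        assert res.critical_value == pytest.approx(crit, abs=1e-12)
        assert res.reject == (T > crit)
        assert res.p_value == pytest.approx(1 - stats.chi2.cdf(T, 1),
                                            abs=1e-12)

    def test_p_value_decreasing_in_T(self, rng):
        n, k = 6, 3
        base = np.corrcoef(rng.normal(size=(n, 50)))
        ps = []
        for delta in (0.0, 0.2, 0.4):
            C2 = base.copy()
            C2[0, 1] = C2[1, 0] = np.clip(base[0, 1] + delta, -1, 1)
            res = lp_test.lp_test(
                lp_test.LPInput([base, base, C2], n_obs=40))
            ps.append((res.T, res.p_value))
        Ts, pvals = zip(*ps)
        assert Ts[0] < Ts[1] < Ts[2]
        assert pvals[0] > pvals[1] > pvals[2]

    def test_reject_iff_T_exceeds_critical(self, rng):
        for seed in range(5):
            mats = synthetic.simulate_correlation_samples(
                block_sigma(12), n_obs=20, k=3, seed=seed)
            res = lp_test.lp_test(lp_test.LPInput(mats, n_obs=20))
            assert res.reject == (res.T > res.critical_value)
            assert 0 <= res.p_value <= 1

    def test_p_value_and_critical_value_consistent(self, rng):
        # p < alpha exactly when T > critical value (the formulas invert
        # each other)
        for seed in range(10):
            mats = synthetic.simulate_correlation_samples(
                block_sigma(10), n_obs=15, k=3, seed=100 + seed)
            res = lp_test.lp_test(lp_test.LPInput(mats, n_obs=15, alpha=0.05))
            assert (res.p_value < res.alpha) == res.reject

    def test_type_one_error_within_mc_band(self):
        # conservatism across alpha levels under a dependent null
        Sigma = block_sigma()
        reps = 200
        results = []
        for rep in range(reps):
            mats = synthetic.simulate_correlation_samples(
                Sigma, n_obs=30, k=3, seed=rep)
            results.append(lp_test.lp_test(
                lp_test.LPInput(mats, n_obs=30, alpha=0.05)))
        for alpha in (0.01, 0.05, 0.1):
            crit = stats.chi2.ppf(lp_test.sidak_epsilon(alpha, 30), df=2)
            rate = np.mean([r.T > crit for r in results])
            se = np.sqrt(alpha * (1 - alpha) / reps)
            assert rate <= alpha + 2 * se


class TestLPOnHic:
    def test_same_sample_twice_accepts(self):
        cfg = synthetic.SimConfig(n_bins=40, block_size=10, seed=5)
        H = synthetic.simulate_hic(cfg)
        res = lp_test.lp_on_hic([H, H])
        assert not res.reject
        assert res.p_value == 1.0

    def test_planted_flip_detected_and_localized(self):
        rejections, localized = 0, 0
        for rep in range(10):
            loci = tuple(range(40, 60))
            cfg = synthetic.SimConfig(n_bins=100, seed=200 + rep,
                                      changed_loci=loci)
            H0 = synthetic.simulate_hic(cfg, t_frac=0.0)
            H1 = synthetic.simulate_hic(cfg, t_frac=1.0)
            res = lp_test.lp_on_hic([H0, H1], region=(20, 80))
            rejections += res.reject
            a, b = res.meta["argmax_bins"]
            localized += (40 <= a < 60) or (40 <= b < 60)
        assert rejections >= 9
        assert localized >= 9

    def test_region_out_of_bounds(self):
        cfg = synthetic.SimConfig(n_bins=20, block_size=5, seed=1)
        H = synthetic.simulate_hic(cfg)
        with pytest.raises(ValidationError):
            lp_test.lp_on_hic([H, H], region=(10, 30))

    def test_n_obs_equals_region_width(self):
        cfg = synthetic.SimConfig(n_bins=50, block_size=10, seed=2)
        H = synthetic.simulate_hic(cfg)
        res = lp_test.lp_on_hic([H, H], region=(5, 25))
        assert res.n_obs == 20


def test_lp_input_validation(rng):
    C = np.corrcoef(rng.normal(size=(5, 20)))
    with pytest.raises(ValidationError, match="k >= 2"):
        lp_test.LPInput([C], n_obs=20)
    with pytest.raises(ValidationError, match="n_obs"):
        lp_test.LPInput([C, C], n_obs=3)
    with pytest.raises(ValidationError, match="alpha"):
        lp_test.LPInput([C, C], n_obs=10, alpha=1.5)
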