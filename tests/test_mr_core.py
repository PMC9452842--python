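import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabomr import SimConfig, cochran_q, egger, harmonize, ivw, \
    mode_based, simulate_two_sample_gwas, wald_ratios, weighted_median
from metabomr.io_formats import ValidationError

from conftest import make_panel


class TestWaldRatios:
    def test_direct_evaluation(self):
        panel = make_panel([0.1], [0.05], [0.01])
        theta, se = wald_ratios(panel)
        assert theta[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.1)

    def test_null_outcome(self):
        theta, _ = wald_ratios(make_panel([0.1], [0.0], [0.01]))
        assert theta[0] == 0.0

    def test_orientation_symmetry(self):
        a, _ = wald_ratios(make_panel([0.1], [0.05], [0.01]))
        b, _ = wald_ratios(make_panel([-0.1], [-0.05], [0.01]))
        assert a[0] == b[0]

    def test_zero_gamma_names_snp(self):
        with pytest.raises(ValidationError, match="rs2"):
            wald_ratios(make_panel([0.1, 0.0], [0.05, 0.01], 0.01))


class TestIvw:
    def test_homogeneous_ratios(self, homogeneous_panel):
        est = ivw(homogeneous_panel, model="auto")
        assert est.beta == pytest.approx(0.5)
        assert est.Q == pytest.approx(0.0, abs=1e-20)
        assert est.method == "ivw_fixed"
        assert ivw(homogeneous_panel, "fixed").se == \
            pytest.approx(ivw(homogeneous_panel, "random").se)

    def test_worked_example(self, worked_panel):
        est = ivw(worked_panel, model="fixed")
        assert est.beta == pytest.approx(980 / 2100, abs=1e-9)
        assert est.se == pytest.approx(1 / np.sqrt(2100), abs=1e-9)
        assert est.Q == pytest.approx(8 / 3, abs=1e-6)
        assert est.Q_pval == pytest.approx(np.exp(-4 / 3), abs=1e-6)

    def test_single_snp_reduces_to_wald(self):
        panel = make_panel([0.1], [0.06], [0.01])
        est = ivw(panel)
        assert est.method == "wald"
        assert est.beta == pytest.approx(0.6)
        assert est.se == pytest.approx(0.1)

    def test_random_inflates_se_only_under_heterogeneity(self, worked_panel):
        fixed = ivw(worked_panel, "fixed")
        random = ivw(worked_panel, "random")
        assert random.beta == fixed.beta
        assert random.se == pytest.approx(fixed.se * np.sqrt(fixed.Q / 2))

    def test_auto_switch_respects_q_alpha(self, worked_panel):
        # Q-p ~ 0.264: random only when the test level exceeds it
        assert ivw(worked_panel, "auto", q_alpha=0.05).method == "ivw_fixed"
        assert ivw(worked_panel, "auto", q_alpha=0.30).method == "ivw_random"

    def test_ci_brackets_beta(self, worked_panel):
        est = ivw(worked_panel)
        lo, hi = est.ci95
        assert lo < est.beta < hi
        assert hi - est.beta == pytest.approx(1.959963984540054 * est.se)

    def test_equals_no_intercept_wls_oracle(self):
        """Fixed-effect IVW is a no-intercept WLS of outcome on exposure
        effects with weights 1/se_Y^2 (random panels, tol 1e-10)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            J = int(rng.integers(2, 30))
            panel = make_panel(rng.uniform(0.05, 0.4, J) * rng.choice([-1, 1], J),
                               rng.normal(0, 0.1, J), rng.uniform(0.005, 0.05, J))
            w = 1.0 / panel.se_y**2
            expected = (np.sum(w * panel.gamma * panel.big_gamma)
                        / np.sum(w * panel.gamma**2))
            assert ivw(panel, "fixed").beta == pytest.approx(expected, abs=1e-10)

    def test_orientation_invariance(self, worked_panel):
        flipped = make_panel(worked_panel.gamma * np.array([1, -1, 1]),
                             worked_panel.big_gamma * np.array([1, -1, 1]),
                             worked_panel.se_y)
        for model in ("fixed", "random"):
            assert ivw(flipped, model).beta == \
                pytest.approx(ivw(worked_panel, model).beta, abs=1e-14)


class TestCochranQ:
    def test_homogeneous_is_zero(self, homogeneous_panel):
        Q, df, p = cochran_q(homogeneous_panel)
        assert Q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_worked_example_chi2_tail(self, worked_panel):
        Q, df, p = cochran_q(worked_panel)
        assert Q == pytest.approx(8 / 3, abs=1e-9)
        assert p == pytest.approx(np.exp(-Q / 2), abs=1e-12)  # df=2 closed form

    def test_permutation_invariance(self, worked_panel):
        perm = worked_panel.subset([2, 0, 1])
        assert cochran_q(perm)[0] == pytest.approx(cochran_q(worked_panel)[0])

    def test_single_snp_rejected(self):
        with pytest.raises(ValidationError):
            cochran_q(make_panel([0.1], [0.05], [0.01]))


class TestEgger:
    def test_exact_line_recovered(self):
        gamma = np.array([0.1, 0.15, 0.2, 0.3, 0.4])
        panel = make_panel(gamma, 0.1 + 0.5 * gamma, 0.01)
        est = egger(panel)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert est.Q == pytest.approx(0.0, abs=1e-16)
        assert est.Q_df == 3

    def test_zero_intercept_matches_wls_oracle(self):
        gamma = np.array([0.1, 0.15, 0.2, 0.3, 0.4])
        rng = np.random.default_rng(3)
        y = 0.5 * gamma + rng.normal(0, 0.01, 5)
        panel = make_panel(gamma, y, 0.01)
        X = np.column_stack([np.ones(5), gamma])
        slope_oracle = np.linalg.lstsq(X, y, rcond=None)[0][1]  # equal weights
        assert egger(panel).beta == pytest.approx(slope_oracle, abs=1e-10)

    def test_orientation_invariance_after_internal_flip(self):
        gamma = np.array([0.1, -0.15, 0.2, -0.3, 0.4])
        rng = np.random.default_rng(4)
        y = 0.5 * gamma + rng.normal(0, 0.01, 5)
        panel = make_panel(gamma, y, 0.01)
        flip = np.array([1, -1, 1, 1, -1.0])
        panel2 = make_panel(gamma * flip, y * flip, 0.01)
        assert egger(panel2).beta == pytest.approx(egger(panel).beta, abs=1e-12)
        assert egger(panel2).egger_intercept == \
            pytest.approx(egger(panel).egger_intercept, abs=1e-12)

    def test_intercept_recovers_directional_pleiotropy(self):
        """Mean Egger intercept over replicates recovers the planted mean
        direct effect (0.05) to within 10%.  Exact agreement is not
        expected: exposure-side sampling noise attenuates the slope and
        pushes a small compensating shift (~beta*(1-lambda)*E|gamma|, here
        ~0.002) into the intercept — the familiar finite-sample behaviour
        of the weighted Egger regression."""
        intercepts = []
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_snps=50, pleiotropy_mode="directional",
                            pleiotropy_mean=0.05, pleiotropy_sd=0.01)
            exposure, outcome, _ = simulate_two_sample_gwas(cfg)
            panel, _ = harmonize(exposure, outcome)
            intercepts.append(egger(panel).egger_intercept)
        assert np.mean(intercepts) == pytest.approx(0.05, abs=0.005)

    def test_too_few_snps(self, worked_panel):
        with pytest.raises(ValidationError):
            egger(worked_panel.subset([0, 1]))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        panel = make_panel([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], 0.01)
        est = weighted_median(panel, n_boot=50, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_constant_ratios(self):
        panel = make_panel([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], 0.01)
        est = weighted_median(panel, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.5)
        assert est.se < 0.2

    def test_bootstrap_seeded(self, worked_panel):
        a = weighted_median(worked_panel, n_boot=100, seed=7)
        b = weighted_median(worked_panel, n_boot=100, seed=7)
        assert a.se == b.se

    def test_robust_to_minority_invalid_instruments(self):
        """With 30% of SNPs given large pleiotropy, the weighted median
        stays closer to the truth than IVW on the same data."""
        rng = np.random.default_rng(11)
        med_err, ivw_err = [], []
        for seed in range(30):
            cfg = SimConfig(seed=seed, n_snps=20, true_beta=0.2)
            exposure, outcome, truth = simulate_two_sample_gwas(cfg)
            bad = rng.choice(20, size=6, replace=False)
            from metabomr import plant_outliers
            outcome = plant_outliers(outcome, bad.tolist(), 0.15)
            panel, _ = harmonize(exposure, outcome)
            med_err.append(abs(weighted_median(panel, n_boot=10, seed=seed).beta - 0.2))
            ivw_err.append(abs(ivw(panel, "fixed").beta - 0.2))
        assert np.mean(med_err) < np.mean(ivw_err)


class TestModeBased:
    def test_point_mass(self):
        panel = make_panel([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], 0.01)
        est = mode_based(panel, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_majority_cluster_beats_outliers(self):
        gamma = np.full(9, 0.2)
        theta = np.array([0.5] * 7 + [2.0] * 2)
        panel = make_panel(gamma, gamma * theta, 0.02)
        est = mode_based(panel, n_boot=10, seed=0)
        ivw_est = ivw(panel, "fixed")
        assert abs(est.beta - 0.5) < 0.15
        assert abs(est.beta - 0.5) < abs(ivw_est.beta - 0.5)

    def test_bootstrap_seeded(self, worked_panel):
        a = mode_based(worked_panel, n_boot=100, seed=3)
        b = mode_based(worked_panel, n_boot=100, seed=3)
        assert a.se == b.se

    @pytest.mark.parametrize("phi", [0, -1.0])
    def test_bad_bandwidth(self, worked_panel, phi):
        with pytest.raises(ValidationError):
            mode_based(worked_panel, phi=phi)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_every_estimator_orientation_invariant(seed):
    """Negating any SNP's (gamma, Gamma) pair leaves all point estimates
    unchanged."""
    rng = np.random.default_rng(seed)
    J = int(rng.integers(4, 15))
    panel = make_panel(rng.uniform(0.05, 0.4, J) * rng.choice([-1, 1], J),
                       rng.normal(0, 0.1, J), rng.uniform(0.005, 0.05, J))
    flip = rng.choice([-1.0, 1.0], J)
    flipped = make_panel(panel.gamma * flip, panel.big_gamma * flip, panel.se_y)
    assert ivw(flipped, "fixed").beta == pytest.approx(ivw(panel, "fixed").beta, abs=1e-12)
    assert egger(flipped).beta == pytest.approx(egger(panel).beta, abs=1e-10)
    assert weighted_median(flipped, n_boot=2, seed=0).beta == \
        pytest.approx(weighted_median(panel, n_boot=2, seed=0).beta, abs=1e-12)
    assert mode_based(flipped, n_boot=2, seed=0).beta == \
        pytest.approx(mode_based(panel, n_boot=2, seed=0).beta, abs=1e-12)


def test_fixed_ivw_coverage_nominal():
    """Over valid-instrument replicates the fixed-effect 95% CI covers the
    true effect at close to the nominal rate."""
    covered = 0
    n_rep = 200
    for seed in range(n_rep):
        cfg = SimConfig(seed=seed, n_snps=50, true_beta=0.2)
        exposure, outcome, _ = simulate_two_sample_gwas(cfg)
        panel, _ = harmonize(exposure, outcome)
        lo, hi = ivw(panel, "fixed").ci95
        covered += lo <= 0.2 <= hi
    assert 0.92 <= covered / n_rep <= 0.98
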