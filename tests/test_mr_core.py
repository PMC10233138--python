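"""The five causal estimators: Wald ratio, IVW, maximum likelihood,
weighted median, and MR-Egger."""

import numpy as np
import pytest

from mrkit import (
    DegenerateInstrumentError,
    HarmonizedPair,
    InstrumentSet,
    InsufficientInstrumentsError,
    egger,
    ivw,
    max_likelihood,
    wald_ratio,
    weighted_median,
)
from mrkit.mr_core import _weighted_median_rows, ratio_statistics

from conftest import random_instruments


def pair(snp="rs1", bx=0.05, sx=0.005, by=0.033, sy=0.027):
    return HarmonizedPair(snp, bx, sx, by, sy)


class TestWaldRatio:
    def test_first_order_ratio_from_printed_phosphorus_row(self):
        est = wald_ratio(pair(bx=0.050, sx=0.005, by=0.033, sy=0.027))
        assert est.ratio == pytest.approx(0.66)
        assert est.se_ratio == pytest.approx(0.54)

    def test_second_order_se_adds_exposure_uncertainty(self):
        first = wald_ratio(pair(), "first")
        second = wald_ratio(pair(), "second")
        expected = np.sqrt(0.027**2 / 0.05**2 + 0.033**2 * 0.005**2 / 0.05**4)
        assert second.se_ratio == pytest.approx(expected)
        assert second.se_ratio > first.se_ratio

    def test_zero_outcome_beta_gives_zero_ratio(self):
        assert wald_ratio(pair(by=0.0)).ratio == 0.0

    def test_sign_flip_symmetry(self):
        a = wald_ratio(pair(bx=0.05, by=0.033))
        b = wald_ratio(pair(bx=-0.05, by=-0.033))
        assert a.ratio == pytest.approx(b.ratio)
        assert a.se_ratio == pytest.approx(b.se_ratio)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(pair(bx=0.0))


class TestIVW:
    def test_iron_reproduces_published_estimate(self, iron):
        est = ivw(iron, "multiplicative_random")
        assert est.or_point == pytest.approx(0.82, abs=0.01)
        assert est.or_low == pytest.approx(0.75, abs=0.01)
        assert est.or_high == pytest.approx(0.90, abs=0.01)
        assert est.pval == pytest.approx(2.16e-5, rel=0.05)

    def test_copper_reproduces_published_or(self, fixture_instruments):
        est = ivw(fixture_instruments["copper"])
        assert round(est.or_point, 2) == 1.02

    def test_single_snp_equals_wald_ratio(self):
        ins = InstrumentSet.from_summary([0.1], [0.01], [0.02], [0.03])
        est = ivw(ins, "multiplicative_random")
        w = wald_ratio(ins.pairs[0])
        assert est.beta == pytest.approx(w.ratio)
        assert est.se == pytest.approx(w.se_ratio)

    def test_fixed_and_random_share_the_point_estimate(self, fixture_instruments):
        for ins in fixture_instruments.values():
            assert ivw(ins, "fixed").beta == ivw(ins, "multiplicative_random").beta

    def test_dispersion_is_not_floored_at_one(self, iron):
        est = ivw(iron, "multiplicative_random")
        assert est.dispersion < 1  # sigma ~0.51 shrinks the fixed SE
        assert est.se == pytest.approx(ivw(iron, "fixed").se * est.dispersion)

    def test_weighted_mean_equals_zero_intercept_regression(self):
        """Dual-computation identity: the IVW weighted mean of ratios equals
        the zero-intercept WLS slope of beta_out on beta_exp (weights
        1/se_out^2), here checked on random instances to 1e-10."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            ins = random_instruments(rng, k=int(rng.integers(2, 12)))
            bx, _, by, sy = ins.arrays()
            w = sy**-2.0
            slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
            assert ivw(ins).beta == pytest.approx(slope, abs=1e-10)

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(5)
        ins = random_instruments(rng, k=8)
        perm = rng.permutation(8)
        shuffled = InstrumentSet(
            ins.exposure, ins.outcome, tuple(ins.pairs[i] for i in perm)
        )
        for mode in ("fixed", "multiplicative_random"):
            assert ivw(ins, mode).beta == pytest.approx(ivw(shuffled, mode).beta, abs=1e-14)
            assert ivw(ins, mode).se == pytest.approx(ivw(shuffled, mode).se, abs=1e-14)


class TestMaxLikelihood:
    def test_matches_ivw_when_exposure_noise_vanishes(self):
        rng = np.random.default_rng(2)
        ins = random_instruments(rng, k=8)
        bx, _, by, sy = ins.arrays()
        exact = InstrumentSet.from_summary(bx, np.full(8, 1e-8), by, sy)
        ml = max_likelihood(exact)
        fe = ivw(exact, "fixed")
        assert ml.beta == pytest.approx(fe.beta, abs=1e-6)

    def test_iron_close_to_ivw(self, iron):
        assert max_likelihood(iron).beta == pytest.approx(ivw(iron).beta, abs=0.02)

    def test_agrees_with_profile_likelihood_grid_search(self, iron):
        """Independent oracle: profile out the latent effects analytically
        and scan theta on a fine grid."""
        bx, sx, by, sy = iron.arrays()

        def profile_nll(theta):
            xi = (bx / sx**2 + theta * by / sy**2) / (1 / sx**2 + theta**2 / sy**2)
            return 0.5 * np.sum((bx - xi) ** 2 / sx**2) + 0.5 * np.sum(
                (by - theta * xi) ** 2 / sy**2
            )

        grid = np.linspace(-1.0, 1.0, 20001)
        oracle = grid[np.argmin([profile_nll(t) for t in grid])]
        assert max_likelihood(iron).beta == pytest.approx(oracle, abs=1e-4)

    def test_negating_outcome_negates_theta(self, iron):
        bx, sx, by, sy = iron.arrays()
        neg = InstrumentSet.from_summary(bx, sx, -by, sy)
        assert max_likelihood(neg).beta == pytest.approx(-max_likelihood(iron).beta, abs=1e-8)


class TestWeightedMedian:
    def test_equal_weights_pick_middle_ratio(self):
        est = _weighted_median_rows(np.array([1.0, 2.0, 10.0]), np.ones(3))
        assert est == pytest.approx(2.0)

    def test_interpolation_matches_hand_evaluation(self):
        """Weights (0.25, 0.75) on ratios (0, 1): midpoints at 0.125 and
        0.625, so the 0.5 quantile interpolates to 0.75."""
        est = _weighted_median_rows(np.array([0.0, 1.0]), np.array([0.25, 0.75]))
        assert est == pytest.approx(0.75)

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            ins = random_instruments(rng, k=int(rng.integers(3, 10)))
            bx, _, by, _ = ins.arrays()
            ratios = by / bx
            est = weighted_median(ins, seed=1)
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_bootstrap_se_vanishes_with_noise(self):
        theta = 0.3
        bx = np.array([0.2, 0.3, 0.4, 0.25])
        tiny = 1e-8
        ins = InstrumentSet.from_summary(bx, np.full(4, tiny), theta * bx, np.full(4, tiny))
        est = weighted_median(ins, seed=3)
        assert est.beta == pytest.approx(theta, abs=1e-6)
        assert est.se < 1e-6

    def test_requires_three_instruments(self, fixture_instruments):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(fixture_instruments["zinc"], seed=1)

    def test_seed_reproducibility(self, iron):
        a = weighted_median(iron, seed=7)
        b = weighted_median(iron, seed=7)
        assert a == b


class TestEgger:
    @pytest.mark.parametrize(
        "name,expected",
        [("iron", 0.009), ("phosphorus", 0.100), ("magnesium", 0.016)],
    )
    def test_intercepts_match_published_values(self, fixture_instruments, name, expected):
        est = egger(fixture_instruments[name])
        assert round(est.intercept, 3) == expected

    def test_exact_proportionality_gives_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        ins = InstrumentSet.from_summary(bx, np.full(4, 0.01), 0.5 * bx, np.full(4, 0.03))
        est = egger(ins)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_requires_three_instruments(self, fixture_instruments):
        with pytest.raises(InsufficientInstrumentsError):
            egger(fixture_instruments["copper"])

    def test_orientation_invariance_under_allele_flips(self, iron):
        """Simultaneously flipping the coded allele of any SNP (negating
        both betas) leaves every estimator unchanged."""
        bx, sx, by, sy = iron.arrays()
        flip = np.array([1, -1, 1, -1, 1.0])
        flipped = InstrumentSet.from_summary(bx * flip, sx, by * flip, sy)
        assert egger(flipped).intercept == pytest.approx(egger(iron).intercept, abs=1e-12)
        assert ivw(flipped).beta == pytest.approx(ivw(iron).beta, abs=1e-12)
        assert max_likelihood(flipped).beta == pytest.approx(max_likelihood(iron).beta, abs=1e-6)
        a = weighted_median(flipped, seed=5)
        b = weighted_median(iron, seed=5)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)


def test_parameter_recovery_without_pleiotropy():
    """With no pleiotropy every estimator's mean estimate sits within
    Monte-Carlo error of the true effect."""
    from mrkit import Pleiotropy, SimulationConfig, recovery_experiment

    config = SimulationConfig(seed=99, k=15, theta=0.15, pleiotropy=Pleiotropy("none"))
    summary = recovery_experiment(
        config, methods=("ivw_mre", "max_likelihood", "weighted_median", "egger_slope"), n_reps=100
    )
    for method, res in summary.items():
        mc_se = res.rmse / np.sqrt(res.n_reps - res.n_failed)
        assert abs(res.mean_bias) < 4 * mc_se + 0.01, method
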