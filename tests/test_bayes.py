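import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isochrom.bayes import (
    BayesModelConfig,
    PosteriorSummary,
    classify_coordination,
    conjugate_oracle,
    fit_group_difference,
    gene_expression_from_isoforms,
    hdi,
    integrate,
)
from isochrom.chromatin import PromoterCall
from isochrom.errors import ConfigError, DataError
from isochrom.io import ExpressionMatrix


def _cfg(**kw):
    kw.setdefault("seed", 42)
    return BayesModelConfig(**kw)


def _exhaustive_hdi(draws, mass):
    """Independent oracle: scan every contiguous window of sorted draws."""
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    k = int(np.ceil(mass * n))
    best = None
    for i in range(n - k + 1):
        w = x[i + k - 1] - x[i]
        if best is None or w < best[0] - 0:
            best = (w, x[i], x[i + k - 1])
    return best[1], best[2]


class TestHdi:
    def test_constant_draws_zero_width(self):
        lo, hi = hdi([3.3] * 100, 0.95)
        assert lo == hi == 3.3

    def test_normal_draws_match_quantile_oracle(self, rng):
        draws = rng.standard_normal(100_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_exponential_upper_bound_analytic(self, rng):
        # the 95% HDI of Exp(1) is (0, -ln 0.05) = (0, 2.996)
        draws = rng.exponential(1.0, 100_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(0.0, abs=0.01)
        assert hi == pytest.approx(2.9957, abs=0.05)

    @pytest.mark.parametrize("n", [25, 100, 1003, 5000])
    def test_matches_exhaustive_window_scan(self, n, rng):
        draws = rng.gamma(2.0, 1.0, n)
        for mass in (0.5, 0.9, 0.95):
            assert hdi(draws, mass) == pytest.approx(_exhaustive_hdi(draws, mass))

    def test_interval_contains_required_mass(self, rng):
        draws = rng.standard_normal(777)
        lo, hi = hdi(draws, 0.9)
        inside = np.sum((draws >= lo) & (draws <= hi))
        assert inside >= int(np.ceil(0.9 * 777))

    def test_too_few_draws_rejected(self):
        with pytest.raises(DataError):
            hdi([1.0, 2.0], 0.95)

    def test_arviz_cross_check(self, rng):
        """Independent implementation agreement on a skewed sample."""
        az = pytest.importorskip("arviz")
        draws = rng.gamma(3.0, 2.0, 20_000)
        ours = hdi(draws, 0.94)
        theirs = az.hdi(draws, hdi_prob=0.94)
        # definitions differ by one draw (ceil vs floor of mass*n)
        assert ours == pytest.approx(tuple(theirs), abs=0.01)


class TestConjugateOracle:
    def test_equal_groups_is_exactly_half(self):
        y = [1.0, 2.0, 3.0]
        assert conjugate_oracle(y, y)[1] == 0.5

    def test_separated_groups_near_one(self, rng):
        p = conjugate_oracle(rng.normal(5, 1, 10), rng.normal(0, 1, 10))[1]
        assert p >= 0.9999

    def test_matches_welch_t_tail(self, rng):
        y1, y2 = rng.normal(1, 1, 8), rng.normal(0, 2, 6)
        md, p = conjugate_oracle(y1, y2)
        t_res = stats.ttest_ind(y1, y2, equal_var=False)
        # one-sided Welch tail is exactly the posterior P(theta > 0)
        assert p == pytest.approx(1 - t_res.pvalue / 2 if md > 0 else t_res.pvalue / 2)


class TestFitGroupDifference:
    def test_identical_groups_symmetric(self):
        y = [4.1, 5.2, 3.9, 5.0, 4.5]
        s = fit_group_difference(y, y, _cfg())
        assert s.prob_gt_zero == pytest.approx(0.5, abs=0.05)

    def test_separated_groups_pass_and_hdi_excludes_zero(self, rng):
        s = fit_group_difference(
            rng.normal(5, 1, 10), rng.normal(0, 1, 10), _cfg()
        )
        assert s.prob_gt_zero > 0.999
        assert s.hdi_low > 0
        assert s.theta_mean == pytest.approx(5.0, abs=1.0)

    def test_group_swap_symmetry(self, rng):
        y1, y2 = rng.normal(0.8, 1, 8), rng.normal(0, 1, 8)
        a = fit_group_difference(y1, y2, _cfg())
        b = fit_group_difference(y2, y1, _cfg())
        assert a.theta_mean == pytest.approx(-b.theta_mean, abs=0.1)
        assert a.prob_gt_zero == pytest.approx(1 - b.prob_gt_zero, abs=0.02)

    def test_deterministic_given_seed(self, rng):
        y1, y2 = rng.normal(1, 1, 5), rng.normal(0, 1, 5)
        a = fit_group_difference(y1, y2, _cfg())
        b = fit_group_difference(y1, y2, _cfg())
        assert (a.theta_mean, a.hdi_low, a.hdi_high, a.prob_gt_zero) == (
            b.theta_mean, b.hdi_low, b.hdi_high, b.prob_gt_zero
        )

    def test_small_group_skipped_not_fabricated(self):
        s = fit_group_difference([1.0], [0.0, 0.5, 1.0], _cfg())
        assert s.status == "skipped:group_too_small"
        assert np.isnan(s.theta_mean)

    def test_zero_pooled_sd_degenerate_point_mass(self):
        s = fit_group_difference([2.0, 2.0], [2.0, 2.0], _cfg())
        assert s.status == "degenerate"
        assert s.theta_mean == 0.0 and s.hdi_low == s.hdi_high == 0.0
        assert s.prob_gt_zero == 0.5

    def test_shift_monotonicity(self, rng):
        y1, y2 = rng.normal(0.5, 1, 6), rng.normal(0, 1, 6)
        base = fit_group_difference(y1, y2, _cfg())
        shifted = fit_group_difference(y1 + 5.0, y2, _cfg())
        assert shifted.prob_gt_zero >= base.prob_gt_zero

    def test_seed_is_mandatory(self):
        with pytest.raises(ConfigError, match="seed"):
            fit_group_difference([1.0, 2.0], [0.0, 1.0], BayesModelConfig())

    def test_convergence_diagnostic_reported(self, rng):
        s = fit_group_difference(rng.normal(0, 1, 8), rng.normal(0, 1, 8), _cfg())
        assert s.converged and s.rhat < 1.1


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw", [{"hdi_mass": 1.2}, {"significance": 0.4}, {"n_burnin": 5000},
               {"sigma_bounds": (0.0, 10.0)}]
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            BayesModelConfig(seed=1, **kw)


def _promoter_calls(status_by_gene, samples):
    calls = []
    for gene, statuses in status_by_gene.items():
        calls.append(
            PromoterCall(
                gene_id=gene, samples=list(samples), status=list(statuses),
                signal=np.ones(len(samples)), peak_id=f"peak_{gene}",
            )
        )
    return calls


class TestIntegrate:
    def _expr(self, rows, samples, conds):
        df = pd.DataFrame(rows, columns=samples)
        df.index = [f"iso{i}" for i in range(len(df))]
        return ExpressionMatrix(df, conds, scale_tag="log2cpm")

    def test_all_open_gene_skipped_with_reason(self):
        samples = ["a", "b", "c", "d"]
        conds = {s: "x" for s in samples}
        expr = self._expr([[1.0, 2, 3, 4]], samples, conds)
        calls = _promoter_calls({"iso0": ["open"] * 4}, samples)
        out = integrate(expr, calls, _cfg(), grouping="per-sample")
        assert out[0].status == "skipped:one_group_empty"

    def test_sample_mismatch_is_error_before_fitting(self):
        samples = ["a", "b", "c", "d"]
        expr = self._expr([[1.0, 2, 3, 4]], samples, {s: "x" for s in samples})
        calls = _promoter_calls({"iso0": ["open", "closed"]}, ["a", "b"])
        with pytest.raises(DataError, match="mismatch"):
            integrate(expr, calls, _cfg())

    def test_deterministic_and_batch_order_independent(self, rng):
        samples = [f"s{i}" for i in range(8)]
        conds = {s: "x" for s in samples}
        rows = rng.normal(5, 1, (6, 8))
        rows[0, :4] += 3.0
        expr = self._expr(rows, samples, conds)
        status = ["open"] * 4 + ["closed"] * 4
        calls = _promoter_calls({f"iso{i}": status for i in range(6)}, samples)
        a = integrate(expr, calls, _cfg())
        b = integrate(expr, calls, _cfg())
        assert [(s.theta_mean, s.prob_gt_zero) for s in a] == [
            (s.theta_mean, s.prob_gt_zero) for s in b
        ]
        assert a[0].theta_mean == pytest.approx(3.0, abs=1.0)

    def test_gene_level_sum_in_linear_space(self):
        samples = ["a", "b"]
        expr = self._expr([[1.0, 2.0], [1.0, 2.0]], samples, {"a": "x", "b": "x"})
        ge = gene_expression_from_isoforms(expr, {"iso0": "g", "iso1": "g"})
        # two isoforms at log2 value v sum to v + 1
        assert ge.loc["g", "a"] == pytest.approx(2.0)
        assert ge.loc["g", "b"] == pytest.approx(3.0)


class TestClassifyCoordination:
    def _summary(self, gene, prob):
        return PosteriorSummary(
            gene_id=gene, theta_mean=1.0, hdi_low=0.5, hdi_high=1.5,
            prob_gt_zero=prob, n_open=3, n_closed=3, converged=True, rhat=1.0,
        )

    def _setup(self, prob, direction):
        samples = ["a", "b"]
        calls = _promoter_calls({"g": ["open", "closed"]}, samples)
        de_peaks = {"more_open": set(), "less_open": set()}
        if direction != "none":
            de_peaks[direction] = {"peak_g"}
        return [self._summary("g", prob)], calls, de_peaks

    def test_above_threshold_more_open_is_open_up(self):
        s, c, d = self._setup(0.9995, "more_open")
        assert classify_coordination(s, c, d, _cfg())[0].coordination == "open_up"

    def test_above_threshold_less_open_is_closed_down(self):
        s, c, d = self._setup(0.9995, "less_open")
        assert classify_coordination(s, c, d, _cfg())[0].coordination == "closed_down"

    def test_exactly_at_threshold_is_null(self):
        """The criterion is strictly greater than 99.9%."""
        s, c, d = self._setup(0.999, "more_open")
        assert classify_coordination(s, c, d, _cfg())[0].coordination == "null"

    def test_no_de_peak_direction_is_null(self):
        s, c, d = self._setup(0.9999, "none")
        assert classify_coordination(s, c, d, _cfg())[0].coordination == "null"
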