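"""The Poisson exact test, FDR adjustment and significance calling."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import nbinom, poisson

from tagdge.dge_test import (
    DGEResult,
    call_deg,
    fdr_adjust,
    log2_ratio,
    prob_y_given_x,
    run_dge,
    two_sided_pvalue,
)


def poisson_integral_oracle(x, y, ratio):
    """Independent oracle: integrate Pois(x; lam) * Pois(y; lam*ratio) dlam.

    The null probability of y given x is the posterior predictive under a
    flat prior on the latent transcript abundance lam.
    """
    val, _ = integrate.quad(
        lambda lam: poisson.pmf(x, lam) * poisson.pmf(y, lam * ratio),
        0,
        np.inf,
        epsabs=1e-12,
        limit=200,
    )
    return val


class TestProbYGivenX:
    def test_balanced_zero_counts(self):
        assert prob_y_given_x(0, 0, 10**6, 10**6) == pytest.approx(0.5)

    def test_equal_counts_closed_form(self):
        # x=y=5, equal depths: C(10,5) / 2^11
        assert prob_y_given_x(5, 5, 10**6, 10**6) == pytest.approx(252 / 2048)

    def test_matches_integration_oracle_on_spot_grid(self):
        for ratio in (0.5, 1.0, 2.0):
            n1 = 10**6
            n2 = int(round(ratio * n1))
            for x, y in [(0, 0), (3, 7), (10, 2), (25, 25), (50, 1)]:
                assert prob_y_given_x(x, y, n1, n2) == pytest.approx(
                    poisson_integral_oracle(x, y, n2 / n1), abs=1e-8
                )

    def test_matches_negative_binomial_identity(self):
        """p(y|x) is NB(x+1 successes, N1/(N1+N2)) — library cross-check."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = int(rng.integers(0, 500))
            y = int(rng.integers(0, 500))
            n1 = int(rng.integers(10**5, 10**7))
            n2 = int(rng.integers(10**5, 10**7))
            assert prob_y_given_x(x, y, n1, n2) == pytest.approx(
                nbinom.pmf(y, x + 1, n1 / (n1 + n2)), rel=1e-10
            )

    def test_large_counts_stay_finite(self):
        p = prob_y_given_x(10**6, 10**6, 10**7, 10**7)
        assert 0 < p < 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prob_y_given_x(-1, 0, 10, 10)

    def test_normalization_sums_to_one(self):
        for ratio in (0.5, 1.0, 2.0):
            n1, n2 = 10**6, int(ratio * 10**6)
            for x in (0, 5, 50, 200):
                upper = int(40 * (x + 1) * max(ratio, 1.0)) + 400
                total = sum(prob_y_given_x(x, y, n1, n2) for y in range(upper))
                assert total == pytest.approx(1.0, abs=1e-10)


class TestTwoSidedPvalue:
    def test_balanced_null_gives_one(self):
        assert two_sided_pvalue(0, 0, 10**6, 10**6) == 1.0

    def test_extreme_imbalance_closed_form(self):
        # S = p(0|100) = (1/2)^101, so p = 2 * (1/2)^101 = 2^-100
        assert two_sided_pvalue(100, 0, 10**6, 10**6) == pytest.approx(
            2.0**-100, rel=1e-10
        )

    def test_matches_high_precision_summation(self):
        x, y, n1, n2 = 50, 50, 10**6, 10**6
        s = sum(prob_y_given_x(x, i, n1, n2) for i in range(y + 1))
        expected = 2 * s if s <= 0.5 else 2 * (1 - s)
        assert two_sided_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-12)

    def test_depends_only_on_depth_ratio(self):
        p1 = two_sided_pvalue(17, 42, 10**6, 2 * 10**6)
        p2 = two_sided_pvalue(17, 42, 5 * 10**5, 10**6)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_clamped_to_unit_interval(self):
        for x in range(0, 30):
            for y in (0, x, 3 * x + 1):
                p = two_sided_pvalue(x, y, 10**6, 10**6)
                assert 0.0 <= p <= 1.0

    def test_more_imbalance_is_more_significant(self):
        ps = [two_sided_pvalue(100, y, 10**6, 10**6) for y in (100, 150, 200, 400)]
        assert ps == sorted(ps, reverse=True)


class TestFdrAdjust:
    def test_single_p_identity(self):
        assert fdr_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_step_up(self):
        # sorted p * m / rank = [.04, .04, .04, .04] after monotone step-up
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert fdr_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_order_preserved(self):
        p = [0.5, 0.001, 0.2]
        fdr = fdr_adjust(p)
        assert fdr[1] == min(fdr)
        assert np.argsort(p).tolist() == np.argsort(fdr).tolist()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "empty, full, expected",
        [(20.29, 5.76, 1.82), (3.16, 0.01, 8.30), (9.34, 1.00, 3.22)],
    )
    def test_published_rpkm_pairs(self, empty, full, expected):
        assert round(log2_ratio(empty, full), 2) == expected

    def test_equal_rpkm_is_zero(self):
        assert log2_ratio(7.7, 7.7) == 0.0

    def test_floor_applies_to_both_sides(self):
        assert log2_ratio(0.0, 0.0) == 0.0
        assert log2_ratio(0.0, 10.24) == pytest.approx(-10.0)


class TestCallDeg:
    def make(self, fdr, ratio):
        return DGEResult("g", p_value=0.0, fdr=fdr, log2_ratio=ratio)

    def test_inclusive_boundaries(self):
        results, n_up, n_down = call_deg([self.make(0.001, 1.0)])
        assert results[0].significant and results[0].direction == "Up"
        assert (n_up, n_down) == (1, 0)

    def test_fold_gate_blocks_significance(self):
        results, n_up, n_down = call_deg([self.make(0.0005, 0.9)])
        assert not results[0].significant and results[0].direction == "NS"

    def test_fdr_gate_blocks_significance(self):
        results, _, _ = call_deg([self.make(0.0011, 3.0)])
        assert not results[0].significant

    def test_down_direction(self):
        _, n_up, n_down = call_deg([self.make(1e-5, -2.0)])
        assert (n_up, n_down) == (0, 1)


class TestRunDge:
    def test_columns_and_consistency(self):
        import pandas as pd

        counts = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "length": [1000, 500, 2000],
                "count_full": [100, 5, 0],
                "count_empty": [400, 5, 80],
            }
        )
        n1 = n2 = 10**6
        out = run_dge(counts, n1, n2)
        assert out["p_value"].tolist() == pytest.approx(
            [two_sided_pvalue(x, y, n1, n2)
             for x, y in [(100, 400), (5, 5), (0, 80)]]
        )
        assert out["fdr"].tolist() == pytest.approx(
            fdr_adjust(out["p_value"]).tolist()
        )
        # gene a: 4x up and tiny p -> called Up; gene b: balanced -> NS
        assert out["direction"].tolist()[:2] == ["Up", "NS"]
        assert out.loc[2, "log2_ratio"] == pytest.approx(
            log2_ratio(1e9 * 80 / (n2 * 2000), 0.01)
        )
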