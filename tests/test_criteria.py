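"""Codelength criteria: integer code, parametric complexities, reductions, selection.

The complexity recursions are checked against independent brute-force
enumeration oracles: the multinomial complexity by summing over every
assignment sequence, the mixture complexity by summing over compositions of n
with multinomial coefficients.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from ietmix import (
    EMMParams,
    aic,
    aic_lvc,
    bic,
    bic_lvc,
    complete_latent,
    dnml,
    em_fit,
    integer_codelength,
    log_c_emm,
    log_c_exp,
    log_c_mult,
    mu_bounds,
    nml_exponential,
    nml_lvc,
    select_model,
)
from ietmix.criteria import IntegerBounds, evaluate_criteria

# ---------------------------------------------------------------------------
# independent oracles


def cmult_brute(n: int, k: int) -> float:
    """Multinomial complexity by enumerating all k^n assignment sequences."""
    total = 0.0
    for z in itertools.product(range(k), repeat=n):
        counts = np.bincount(z, minlength=k)
        total += math.prod((c / n) ** c for c in counts if c > 0)
    return total


def c_exp_one(r: int, m_range: int) -> float:
    """Single-exponential complexity (r/e)^r * m_range / Gamma(r); 1 at r=0."""
    if r == 0:
        return 1.0
    return math.exp(r * math.log(r) - r - gammaln(r)) * m_range


def cemm_brute(n: int, k: int, m_range: int) -> float:
    """Mixture complexity by summing over compositions of n into k parts."""
    total = 0.0
    for comp in itertools.product(range(n + 1), repeat=k):
        if sum(comp) != n:
            continue
        multinom = math.exp(gammaln(n + 1) - sum(gammaln(c + 1) for c in comp))
        weight = math.prod((c / n) ** c for c in comp if c > 0)
        total += multinom * weight * math.prod(c_exp_one(c, m_range) for c in comp)
    return total


def completed_fixture():
    """tau = {1,3,10,30} hard-assigned {1,1},{10,30}: counts (2,2), means (2,20)."""
    tau = np.array([1.0, 3.0, 10.0, 30.0])
    params = EMMParams(np.array([0.5, 0.5]), np.array([2.0, 20.0]))
    return tau, complete_latent(tau, params)


# ---------------------------------------------------------------------------


class TestIntegerCodelength:
    def test_sign_symmetry(self):
        for m in range(0, 50):
            assert integer_codelength(m) == integer_codelength(-m)

    def test_nondecreasing_in_magnitude(self):
        values = [integer_codelength(m) for m in range(0, 10_000)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_kraft_inequality(self):
        total = sum(math.exp(-integer_codelength(m)) for m in range(-200_000, 200_001))
        assert total <= 1.0


class TestExponentialNml:
    def test_log_c_exp_n1_unit_range(self):
        assert log_c_exp(1, 0, 1) == pytest.approx(-1.0)

    def test_two_equal_values(self):
        cv = nml_exponential(np.array([1.0, 1.0]), IntegerBounds(0, 1))
        base = cv.components["fit"] + cv.components["complexity"]
        assert base == pytest.approx(2 * math.log(2), rel=1e-12)

    def test_stirling_limit(self):
        n = 100_000
        val = log_c_exp(n, 0, 1)
        assert val == pytest.approx(0.5 * math.log(n / (2 * math.pi)), abs=1e-3)

    def test_mean_outside_bounds_raises(self):
        with pytest.raises(ValueError, match="widen"):
            nml_exponential(np.array([100.0, 120.0]), IntegerBounds(0, 1))


class TestMuBounds:
    def test_floor_ceil_of_log_means(self):
        _, cf = completed_fixture()
        b = mu_bounds(cf)
        assert (b.m_min, b.m_max) == (0, 3)

    def test_degenerate_unit_mean_widened(self):
        cf = complete_latent(np.array([1.0, 1.0]), EMMParams([1.0], [1.0]))
        b = mu_bounds(cf)
        assert (b.m_min, b.m_max) == (0, 1)

    def test_mean_e_widened(self):
        cf = complete_latent(np.full(3, math.e), EMMParams([1.0], [1.0]))
        b = mu_bounds(cf)
        assert (b.m_min, b.m_max) == (1, 2)


class TestCmult:
    def test_single_category_is_one(self):
        for n in (1, 2, 10, 100, 1000):
            assert log_c_mult(n, 1) == 0.0

    def test_small_closed_forms(self):
        assert math.exp(log_c_mult(2, 2)) == pytest.approx(2.5, rel=1e-12)
        assert math.exp(log_c_mult(1, 3)) == pytest.approx(3.0, rel=1e-12)

    @pytest.mark.parametrize("n", range(1, 9))
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_recursion_matches_enumeration(self, n, k):
        assert log_c_mult(n, k) == pytest.approx(
            math.log(cmult_brute(n, k)), rel=1e-9, abs=1e-9
        )


class TestCemm:
    def test_base_case_n2(self):
        assert math.exp(log_c_emm(2, 1, 1)) == pytest.approx(4 / math.e**2, rel=1e-12)

    def test_n1_k2_closed_form(self):
        for R in (1, 3, 7):
            assert math.exp(log_c_emm(1, 2, R)) == pytest.approx(
                2 * R / math.e, rel=1e-12
            )

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 12])
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_recursion_matches_composition_sum(self, n, k):
        for m_range in (1, 3):
            assert log_c_emm(n, k, m_range) == pytest.approx(
                math.log(cemm_brute(n, k, m_range)), rel=1e-9, abs=1e-9
            )

    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_monotone_in_k(self, n):
        vals = [log_c_emm(n, k, 2) for k in range(1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestAicBicFamilies:
    def test_aic_bic_k1_closed_form(self, exponential_sample):
        fit = em_fit(exponential_sample, 1, seed=0)
        n = len(exponential_sample)
        mu = exponential_sample.mean()
        neg_ll = n * math.log(mu) + n
        assert aic(fit).score == pytest.approx(neg_ll + 1, rel=1e-12)
        assert bic(fit).score == pytest.approx(neg_ll + 0.5 * math.log(n), rel=1e-12)

    def test_lvc_penalties(self):
        _, cf = completed_fixture()
        assert aic_lvc(cf).score == pytest.approx(
            cf.joint_neg_loglik + 3, rel=1e-12
        )
        expected_bic = (
            cf.joint_neg_loglik + 0.5 * math.log(4) + 0.5 * (math.log(2) + math.log(2))
        )
        assert bic_lvc(cf).score == pytest.approx(expected_bic, rel=1e-12)

    def test_lvc_equals_plain_for_k1(self, exponential_sample):
        fit = em_fit(exponential_sample, 1, seed=0)
        assert aic_lvc(fit.completed).score == pytest.approx(
            aic(fit).score, rel=1e-10
        )
        assert bic_lvc(fit.completed).score == pytest.approx(
            bic(fit).score, rel=1e-10
        )


class TestNmlLvcAndDnml:
    def test_nml_lvc_fixture_decomposition(self):
        _, cf = completed_fixture()
        cv = nml_lvc(cf, IntegerBounds(0, 3))
        assert cv.components["fit"] == pytest.approx(cf.joint_neg_loglik)
        assert cv.components["complexity"] == pytest.approx(log_c_emm(4, 2, 3))

    def test_dnml_fixture_term_by_term(self):
        _, cf = completed_fixture()
        cv = dnml(cf, IntegerBounds(0, 3))
        cond = (
            (2 * math.log(2) + 2 * math.log(2) - 0.0)
            + (2 * math.log(20) + 2 * math.log(2) - 0.0)
            + 2 * math.log(3)
        )
        # C_mult(4, 2) by enumerating the binomial sum: 103/32
        latent = 4 * math.log(2) + math.log(103 / 32)
        assert cv.components["fit"] == pytest.approx(cond, rel=1e-12)
        assert cv.components["latent"] == pytest.approx(latent, rel=1e-12)

    def test_singleton_component_contribution(self):
        # a component holding a single point contributes just log(mu_hat)
        tau = np.array([1.0, 1.2, 500.0])
        cf = complete_latent(tau, EMMParams([0.5, 0.5], [1.0, 500.0]))
        cv = dnml(cf)
        b = mu_bounds(cf)
        n1 = cf.counts[0]
        mu1 = cf.means_hat[0]
        expected = (
            n1 * math.log(mu1) + n1 * math.log(n1) - gammaln(n1)
            + math.log(500.0)  # the singleton's mean
            + 2 * math.log(b.m_range)
        )
        assert cv.components["fit"] == pytest.approx(expected, rel=1e-12)

    def test_k1_reduction_to_single_exponential_nml(self):
        # for k* = 1 both NML_LVC and DNML collapse to the exponential NML
        rng = np.random.default_rng(42)
        for _ in range(100):
            tau = rng.exponential(rng.uniform(0.1, 50), size=rng.integers(5, 200))
            cf = complete_latent(tau, EMMParams([1.0], [tau.mean()]))
            b = mu_bounds(cf)
            ref = nml_exponential(tau, b).score
            assert nml_lvc(cf, b).score == pytest.approx(ref, rel=1e-9)
            assert dnml(cf, b).score == pytest.approx(ref, rel=1e-9)

    def test_widening_bounds_increases_score(self):
        _, cf = completed_fixture()
        narrow = nml_lvc(cf, IntegerBounds(0, 3))
        wide = nml_lvc(cf, IntegerBounds(0, 6))
        assert (
            wide.components["fit"] + wide.components["complexity"]
            > narrow.components["fit"] + narrow.components["complexity"]
        )


class TestScoreDecomposition:
    def test_components_sum_to_score_for_all_criteria(self, two_component_sample):
        fit = em_fit(two_component_sample, 3, seed=1)
        for cv in evaluate_criteria(fit).values():
            assert sum(cv.components.values()) == pytest.approx(cv.score, rel=1e-9)


class TestSelectModel:
    def test_single_candidate_grid(self, exponential_sample):
        report = select_model(exponential_sample, k_grid=(1,), n_restarts=2, seed=0)
        assert all(sel == (1, 1) for sel in report.selected.values())

    def test_selected_minimises_score(self, two_component_sample):
        report = select_model(
            two_component_sample, k_grid=(1, 2, 3), criteria=("DNML",), n_restarts=3,
            seed=0,
        )
        k_sel, _ = report.selected["DNML"]
        scores = {k: cv.score for k, cv in report.table["DNML"].items()}
        assert scores[k_sel] == min(scores.values())

    def test_two_component_data_selects_two(self, two_component_sample):
        report = select_model(
            two_component_sample, k_grid=(1, 2, 3, 4), n_restarts=5, seed=0,
        )
        for crit in ("AIC_LVC", "BIC_LVC", "NML_LVC", "DNML"):
            assert report.selected[crit][1] == 2

    def test_k_larger_than_n_collapses(self):
        rng = np.random.default_rng(1)
        tau = rng.exponential(1.0, size=6)
        report = select_model(tau, k_grid=(10,), criteria=("DNML",), n_restarts=2, seed=0)
        assert report.table["DNML"][10].k_star <= 6

    def test_report_serialisation(self, tmp_path, exponential_sample):
        report = select_model(
            exponential_sample, k_grid=(1, 2), criteria=("DNML", "BIC"), n_restarts=2,
            seed=0,
        )
        report.to_json(tmp_path / "report.json")
        report.to_tsv(tmp_path / "report.tsv")
        assert (tmp_path / "report.json").stat().st_size > 0
        lines = (tmp_path / "report.tsv").read_text().strip().splitlines()
        assert len(lines) == 1 + 2 * 2
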