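import itertools
import math

import numpy as np
import pytest
from scipy import stats

from stripalloc import (
    AcceptanceSequenceLaw,
    at_least_bahadur,
    at_least_exact,
    at_least_independent,
    cumulative_result,
    law_from_chain,
    nth_probability,
    random_config,
)

from conftest import make_alternation_config, make_single_center_config


class TestExactEngine:
    def test_boundary_contract(self, italy):
        res = at_least_exact(italy, "NITp", 5)
        assert res.probability(0) == 1.0
        assert res.probability(6) == 0.0
        diffs = np.diff([res.probability(k) for k in range(7)])
        assert np.all(diffs <= 1e-15)

    def test_consistency_with_first_model_at_m_equal_one(self, italy):
        first = nth_probability(italy, 1)[0]
        for cid, p in first.probabilities.items():
            res = at_least_exact(italy, cid, 1)
            assert res.probability(1) == pytest.approx(p, abs=1e-12)

    def test_strict_alternation_of_two_greedy_centers(self):
        cfg = make_alternation_config()
        for cid in ("X", "Y"):
            res = at_least_exact(cfg, cid, 2)
            assert res.probability(1) == pytest.approx(1.0, abs=1e-12)
            assert res.probability(2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p", [0.26, 0.9, 1.0])
    def test_single_center_reduces_to_binomial_tail(self, p):
        cfg = make_single_center_config(p)
        M = 20
        res = at_least_exact(cfg, "X", M)
        for k in range(M + 1):
            expected = float(stats.binom.sf(k - 1, M, p))
            assert res.probability(k) == pytest.approx(expected, abs=1e-12)

    def test_greedy_center_extinction_beyond_routable_organs(self):
        # with acceptance rate 1 a center cannot obtain more organs than the
        # round-robin rotation routes to it
        cfg = make_alternation_config()
        res = at_least_exact(cfg, "X", 6)
        assert res.probability(3) == pytest.approx(1.0, abs=1e-12)
        assert res.probability(4) == pytest.approx(0.0, abs=1e-12)


class TestIndependentEngine:
    def test_iid_case_is_the_binomial_tail(self):
        law = AcceptanceSequenceLaw.independent(np.full(12, 0.26))
        for k in range(13):
            assert at_least_independent(law, k) == pytest.approx(
                float(stats.binom.sf(k - 1, 12, 0.26)), abs=1e-12
            )

    def test_heterogeneous_case_matches_full_enumeration(self):
        p = np.array([0.2, 0.5, 0.9])
        law = AcceptanceSequenceLaw.independent(p)
        for k in range(4):
            brute = sum(
                math.prod(pi if b else 1 - pi for pi, b in zip(p, bits))
                for bits in itertools.product((0, 1), repeat=3)
                if sum(bits) >= k
            )
            assert at_least_independent(law, k) == pytest.approx(brute, abs=1e-12)

    def test_empty_requirement_is_certain(self):
        law = AcceptanceSequenceLaw.independent(np.array([0.1, 0.9]))
        assert at_least_independent(law, 0) == 1.0
        assert at_least_independent(law, 3) == 0.0


class TestBahadurEngine:
    def test_zero_correlation_is_bitwise_independent(self):
        rng = np.random.default_rng(0)
        p = rng.random(9)
        law = AcceptanceSequenceLaw.independent(p)
        for k in range(10):
            assert at_least_bahadur(law, k) == at_least_independent(law, k)

    def test_two_variable_closed_form(self):
        # exact correlated pair: P(1,1) = p1 p2 + r sd1 sd2
        p1 = p2 = 0.5
        r = 0.5
        law = AcceptanceSequenceLaw(
            marginals=np.array([p1, p2]),
            correlations=np.array([[1.0, r], [r, 1.0]]),
        )
        sd = math.sqrt(p1 * (1 - p1)) * math.sqrt(p2 * (1 - p2))
        assert at_least_bahadur(law, 2) == pytest.approx(p1 * p2 + r * sd, abs=1e-12)

    def test_exchangeable_case_matches_density_enumeration(self):
        M, p, r = 4, 0.3, 0.2
        corr = np.full((M, M), r)
        np.fill_diagonal(corr, 1.0)
        law = AcceptanceSequenceLaw(marginals=np.full(M, p), correlations=corr)
        # enumerate the second-order truncated density over all 2^4 outcomes,
        # aggregate on the count, clip negatives and renormalize if needed
        sd = math.sqrt(p * (1 - p))
        pmf = np.zeros(M + 1)
        for bits in itertools.product((0, 1), repeat=M):
            base = math.prod(p if b else 1 - p for b in bits)
            z = [(b - p) / sd for b in bits]
            corr_term = sum(
                r * z[s] * z[t] for s in range(M) for t in range(s + 1, M)
            )
            pmf[sum(bits)] += base * (1 + corr_term)
        clipped = -pmf[pmf < 0].sum()
        if clipped > 0:
            pmf = np.clip(pmf, 0, None)
            pmf /= pmf.sum()
        for k in range(M + 1):
            expected = pmf[k:].sum() if k else 1.0
            assert at_least_bahadur(law, k) == pytest.approx(expected, abs=1e-12)

    def test_clipped_mass_is_reported_and_result_monotone(self):
        # strong negative correlation forces negative truncated masses
        M = 3
        corr = np.full((M, M), -0.9)
        np.fill_diagonal(corr, 1.0)
        law = AcceptanceSequenceLaw(marginals=np.full(M, 0.5), correlations=corr)
        res = cumulative_result(law, "bahadur")
        assert res.clipped_mass > 0
        vals = [res.probability(k) for k in range(M + 2)]
        assert vals[0] == 1.0 and vals[-1] == 0.0
        assert np.all(np.diff(vals) <= 1e-15)

    def test_asymmetric_correlations_rejected(self):
        with pytest.raises(ValueError):
            AcceptanceSequenceLaw(
                marginals=np.array([0.5, 0.5]),
                correlations=np.array([[1.0, 0.2], [0.3, 1.0]]),
            )


class TestLawFromChain:
    def test_forced_alternation_yields_negative_successive_correlation(self):
        cfg = make_alternation_config()
        law = law_from_chain(cfg, "X", 4)
        assert law.marginals == pytest.approx([1, 0, 1, 0], abs=1e-12)
        # deterministic alternation makes the indicators degenerate, so their
        # correlations default to 0 by convention
        assert np.all(law.correlations == np.eye(4))
        # soften the rates slightly: closed form by hand for two organs.
        # X accepts organ 1 w.p. r; afterwards the strip is [Y, X] so it
        # accepts organ 2 w.p. (1-r)r; if X refused organ 1 the strip is
        # back to [X, Y] (total-refusal stasis or Y's acceptance rotating
        # both slots), so it accepts organ 2 w.p. r.
        r = 0.999
        p1, p2 = r, r * (1 - r) * r + (1 - r) * r
        p12 = r * (1 - r) * r
        expected = (p12 - p1 * p2) / math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        soft = cfg.with_uniform_rate(r)
        law = law_from_chain(soft, "X", 2)
        assert law.correlations[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rates_give_degenerate_law(self, italy):
        law = law_from_chain(italy.with_uniform_rate(0.0), "NITp", 3)
        assert np.all(law.marginals == 0.0)
        assert np.all(law.correlations == np.eye(3))

    def test_marginals_match_first_model(self, italy):
        law = law_from_chain(italy, "Toscana", 6)
        res = nth_probability(italy, 6)
        for t in range(6):
            assert law.marginals[t] == pytest.approx(
                res[t].probabilities["Toscana"], abs=1e-12
            )

    def test_state_space_overflow_falls_back_to_simulation(self, italy):
        exact = law_from_chain(italy, "NITp", 3)
        assert exact.standard_errors is None
        law = law_from_chain(italy, "NITp", 3, state_cap=2, mc_reps=400, seed=5)
        assert law.standard_errors is not None
        assert np.all(
            np.abs(law.marginals - exact.marginals) <= 4 * law.standard_errors + 1e-9
        )

    @pytest.mark.parametrize("seed", [0, 4])
    def test_chain_joints_are_valid_probabilities(self, seed):
        cfg = random_config(seed)
        cid = cfg.centers[-1].id
        law = law_from_chain(cfg, cid, 5)
        assert np.all(law.marginals >= 0) and np.all(law.marginals <= 1)
        assert np.all(np.abs(law.correlations) <= 1.0)
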