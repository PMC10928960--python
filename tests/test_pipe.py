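"""PIPE design: priors, contour enumeration/posterior, overdose q, dosing."""

from itertools import product
from math import comb as binom

import numpy as np
import pytest

from combocal.grid import DoseGrid, TrialState
from combocal.pipe import (
    PipeDesign,
    cell_below_prob,
    closest_below,
    contour_posterior,
    contour_scores,
    enumerate_contours,
    pipe_build_prior,
    pipe_overdose_q,
)


class TestPrior:
    def test_anti_diagonal_levels(self):
        prior = pipe_build_prior(0.05, 0.025, 1 / 18, DoseGrid(3, 3), parametrisation="mean")
        means = prior.means
        # segments i+j-1 = 1..5 with elicited levels 0.05, 0.075, ..., 0.15
        for i, j in product(range(3), range(3)):
            assert means[i, j] == pytest.approx(0.05 + (i + j) * 0.025, abs=1e-12)

    def test_mean_parametrisation_ess_split(self):
        prior = pipe_build_prior(0.05, 0.0, 1 / 18, DoseGrid(2, 2), parametrisation="mean")
        assert prior.a[0, 0] == pytest.approx(0.05 / 18)
        assert prior.b[0, 0] == pytest.approx(0.95 / 18)

    def test_median_parametrisation_matches_median(self):
        prior = pipe_build_prior(0.05, 0.025, 1 / 18, DoseGrid(3, 3))
        med = prior.medians()
        for i, j in product(range(3), range(3)):
            assert med[i, j] == pytest.approx(0.05 + (i + j) * 0.025, abs=1e-6)
            assert prior.a[i, j] + prior.b[i, j] == pytest.approx(1 / 18)

    def test_delta_zero_flat(self):
        prior = pipe_build_prior(0.1, 0.0, 1.0, DoseGrid(2, 3))
        assert np.allclose(prior.a, prior.a[0, 0])

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            pipe_build_prior(0.5, 0.2, 1.0, DoseGrid(3, 3))


class TestContours:
    @pytest.mark.parametrize("shape,count", [((3, 3), 20), ((1, 1), 2), ((2, 3), 10)])
    def test_counts(self, shape, count):
        assert enumerate_contours(DoseGrid(*shape)).shape[0] == count

    def test_counts_match_binomial_and_bruteforce(self):
        for I, J in [(1, 2), (2, 2), (2, 3), (3, 3), (2, 4), (4, 4)]:
            contours = enumerate_contours(DoseGrid(I, J))
            assert contours.shape[0] == binom(I + J, I)
            # brute-force: filter all binary matrices for bimonotonicity
            if I * J <= 9:
                brute = 0
                for bits in product([0, 1], repeat=I * J):
                    m = np.array(bits).reshape(I, J)
                    if np.all(np.diff(m, axis=0) >= 0) and np.all(np.diff(m, axis=1) >= 0):
                        brute += 1
                assert contours.shape[0] == brute
            # each enumerated contour is monotone; enumeration has no duplicates
            assert np.all(np.diff(contours, axis=1) >= 0)
            assert np.all(np.diff(contours, axis=2) >= 0)
            assert len({c.tobytes() for c in contours}) == contours.shape[0]

    def test_grid_guard(self):
        with pytest.raises(ValueError):
            enumerate_contours(DoseGrid(5, 5))


class TestBelowProb:
    def test_uniform_prior_no_data(self):
        st = TrialState(DoseGrid(1, 1))
        prior = pipe_build_prior(0.5, 0, 2.0, DoseGrid(1, 1), parametrisation="mean")
        # Beta(1,1) prior: P(pi <= 0.3) = 0.3
        assert cell_below_prob(st, prior, 0.3)[0, 0] == pytest.approx(0.3)

    def test_safe_cohort(self):
        st = TrialState(DoseGrid(1, 1))
        st.record_cohort((1, 1), (0, 0, 0))
        prior = pipe_build_prior(0.5, 0, 2.0, DoseGrid(1, 1), parametrisation="mean")
        # Beta(1,4): P(pi <= 0.3) = 1 - 0.7^4
        assert cell_below_prob(st, prior, 0.3)[0, 0] == pytest.approx(1 - 0.7**4, abs=1e-9)

    def test_all_toxic_monotone_in_n(self):
        prior = pipe_build_prior(0.5, 0, 2.0, DoseGrid(1, 1), parametrisation="mean")
        prev = 1.0
        for n in range(1, 13):
            st = TrialState(DoseGrid(1, 1))
            st.record_cohort((1, 1), tuple([1] * n))
            p = float(cell_below_prob(st, prior, 0.3)[0, 0])
            assert p < prev
            prev = p


class TestContourPosterior:
    def test_two_factor_product(self):
        p = np.array([[0.9, 0.6]])
        contour = np.array([[0, 1]])
        assert contour_posterior(p, contour) == pytest.approx(0.9 * 0.4)

    def test_certain_below(self):
        p = np.ones((2, 2))
        assert contour_posterior(p, np.zeros((2, 2), dtype=int)) == pytest.approx(1.0)

    def test_scores_need_not_sum_to_one(self):
        contours = enumerate_contours(DoseGrid(2, 2))
        p = np.full((2, 2), 0.6)
        total = contour_scores(p, contours).sum()
        assert total != pytest.approx(1.0, abs=1e-3)


class TestOverdoseQ:
    def test_single_certain_contour(self):
        contours = enumerate_contours(DoseGrid(1, 2))
        # p chosen so one contour has (numerically) all the mass
        p = np.array([[1.0, 0.0]])
        q = pipe_overdose_q(p, contours)
        np.testing.assert_allclose(q, [[0.0, 1.0]], atol=1e-12)

    def test_uniform_1x1(self):
        contours = enumerate_contours(DoseGrid(1, 1))
        q = pipe_overdose_q(np.array([[0.5]]), contours)
        assert q[0, 0] == pytest.approx(0.5)

    def test_matches_exhaustive_enumeration_2x2(self, rng):
        contours = enumerate_contours(DoseGrid(2, 2))
        for _ in range(25):
            p = rng.uniform(0.05, 0.95, size=(2, 2))
            scores = np.array([contour_posterior(p, c) for c in contours])
            w = scores / scores.sum()
            expect = sum(wi * c for wi, c in zip(w, contours.astype(float)))
            np.testing.assert_allclose(pipe_overdose_q(p, contours), expect, atol=1e-12)

    def test_q_monotone_in_dose(self, rng):
        contours = enumerate_contours(DoseGrid(3, 3))
        for _ in range(10):
            q = pipe_overdose_q(rng.uniform(0.05, 0.95, size=(3, 3)), contours)
            assert np.all(np.diff(q, axis=0) >= -1e-12)
            assert np.all(np.diff(q, axis=1) >= -1e-12)

    def test_transpose_symmetry_no_data(self):
        contours = enumerate_contours(DoseGrid(3, 3))
        p = np.full((3, 3), 0.5)
        q = pipe_overdose_q(p, contours)
        np.testing.assert_allclose(q, q.T, atol=1e-12)


class TestClosestBelow:
    def test_all_safe_contour_upper_boundary(self):
        contour = np.zeros((3, 3), dtype=int)
        assert set(closest_below(contour)) == {(3, 1), (3, 2), (3, 3), (1, 3), (2, 3)}

    def test_interior_boundary(self):
        contour = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]])
        assert set(closest_below(contour)) == {(1, 2), (2, 1)}

    def test_all_toxic_contour_empty(self):
        assert closest_below(np.ones((2, 2), dtype=int)) == []


class TestDesignBehaviour:
    def test_first_escalation_candidates(self, grid33):
        # all-safe modal contour: candidates from (1,1) are the two single-drug
        # escalations, drawn by inverse-sample-size weights
        design = PipeDesign(epsilon=1.0)
        seen = set()
        for k in range(40):
            ctrl = design.new_trial(grid33)
            st = TrialState(grid33)
            st.record_cohort((1, 1), (0, 0, 0))
            seen.add(ctrl.next_combination(st, np.random.default_rng(k)))
        assert seen == {(2, 1), (1, 2)}

    def test_inverse_sample_size_weighting(self, grid33):
        # candidate with n=3 carries weight 1/4 against 1 for untested
        design = PipeDesign(epsilon=1.0)
        counts = {(2, 1): 0, (1, 2): 0}
        reps = 4000
        for k in range(reps):
            ctrl = design.new_trial(grid33)
            st = TrialState(grid33)
            st.record_cohort((1, 1), (0, 0, 0))
            st.record_cohort((2, 1), (0, 0, 0))
            st.current = (1, 1)
            nxt = ctrl.next_combination(st, np.random.default_rng(k))
            if nxt in counts:
                counts[nxt] += 1
        frac_12 = counts[(1, 2)] / (counts[(1, 2)] + counts[(2, 1)])
        assert frac_12 == pytest.approx(4 / 5, abs=0.03)

    def test_stop_on_toxic_lowest_dose(self, grid33, rng):
        design = PipeDesign()  # calibrated epsilon = 0.50
        ctrl = design.new_trial(grid33)
        st = TrialState(grid33)
        for _ in range(3):
            st.record_cohort((1, 1), (1, 1, 1))
        assert ctrl.next_combination(st, rng) is None
        assert st.stopped
        assert ctrl.recommend(st, rng) is None

    def test_final_mtc_posterior_mean_rule(self, grid33, rng):
        design = PipeDesign(epsilon=1.0)
        ctrl = design.new_trial(grid33)
        st = TrialState(grid33)
        # (1,2) near-target data; (2,1) clearly safe; upper cells toxic
        st.record_cohort((1, 2), (1, 0, 0))
        st.record_cohort((1, 2), (0, 0, 0))
        st.record_cohort((2, 1), (0, 0, 0))
        for _ in range(2):
            st.record_cohort((2, 2), (1, 1, 1))
        rec = ctrl.recommend(st, rng)
        assert rec == (1, 2)
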