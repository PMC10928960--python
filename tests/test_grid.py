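"""Shared dose-grid primitives: moves, Beta updates, matrix isotonic regression."""

import numpy as np
import pytest
from scipy.optimize import minimize

from combocal.grid import (
    BetaParams,
    DoseGrid,
    TrialState,
    admissible_moves,
    beta_tail_prob,
    isotonic_1d,
    matrix_isotonic,
    posterior_beta,
    select_mtc_isotonic,
)


class TestAdmissibleMoves:
    @pytest.mark.parametrize(
        "current,family,shape,expected",
        [
            # single-drug moves plus staying (the circle cells of the move diagram)
            ((2, 2), "orthogonal", (4, 4), {(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)}),
            # diagonal de-escalation and anti-diagonal escalation added (star cells)
            (
                (2, 2),
                "extended",
                (4, 4),
                {(2, 2), (1, 2), (3, 2), (2, 1), (2, 3), (1, 1), (3, 1), (1, 3)},
            ),
            ((1, 1), "extended", (3, 3), {(1, 1), (2, 1), (1, 2)}),
            ((1, 1), "orthogonal", (1, 1), {(1, 1)}),
        ],
    )
    def test_families(self, current, family, shape, expected):
        assert admissible_moves(current, family, DoseGrid(*shape)) == expected

    def test_simultaneous_escalation_never_admissible(self):
        # exhaustive over every cell of every grid up to 4x4, both families
        for I in range(1, 5):
            for J in range(1, 5):
                g = DoseGrid(I, J)
                for c in g.combinations():
                    for fam in ("orthogonal", "extended"):
                        moves = admissible_moves(c, fam, g)
                        assert (c[0] + 1, c[1] + 1) not in moves
                        assert all(g.contains(m) for m in moves)

    def test_eliminated_cells_excluded(self, grid33):
        moves = admissible_moves((2, 2), "extended", grid33, {(3, 2), (1, 1)})
        assert (3, 2) not in moves and (1, 1) not in moves

    def test_invalid_inputs(self, grid33):
        with pytest.raises(IndexError):
            admissible_moves((0, 1), "orthogonal", grid33)
        with pytest.raises(ValueError):
            admissible_moves((1, 1), "diagonal", grid33)


class TestBetaPosterior:
    @pytest.mark.parametrize(
        "y,n,prior,expected",
        [
            (0, 0, (1, 1), (1, 1)),
            (1, 3, (1, 1), (2, 3)),
            (2, 6, (0.5, 9.5), (2.5, 13.5)),
        ],
    )
    def test_conjugate_update(self, y, n, prior, expected):
        post = posterior_beta(y, n, BetaParams(*prior))
        assert (post.alpha, post.beta) == expected

    def test_batch_coherence(self, rng):
        # updating on split data equals a single-batch update
        for _ in range(25):
            n1, n2 = rng.integers(0, 10, size=2)
            y1 = rng.integers(0, n1 + 1)
            y2 = rng.integers(0, n2 + 1)
            prior = BetaParams(float(rng.uniform(0.1, 3)), float(rng.uniform(0.1, 3)))
            split = posterior_beta(y2, n2, posterior_beta(y1, n1, prior))
            batch = posterior_beta(y1 + y2, n1 + n2, prior)
            assert split.alpha == pytest.approx(batch.alpha, rel=1e-14)
            assert split.beta == pytest.approx(batch.beta, rel=1e-14)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            posterior_beta(4, 3, BetaParams(1, 1))
        with pytest.raises(ValueError):
            posterior_beta(-1, 3, BetaParams(1, 1))

    @pytest.mark.parametrize(
        "params,threshold,expected",
        [
            ((1, 1), 0.3, 0.7),
            # 1 - (6t^2 - 8t^3 + 3t^4) at t = 0.3 for Beta(2, 3)
            ((2, 3), 0.3, 0.6517),
            ((1, 1), 0.999, 0.001),
        ],
    )
    def test_tail_probability(self, params, threshold, expected):
        assert beta_tail_prob(BetaParams(*params), threshold) == pytest.approx(expected, abs=1e-4)


def _qp_isotonic_oracle(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Brute-force weighted projection onto the bimonotone cone (SLSQP)."""
    I, J = values.shape
    cons = []
    for i in range(I):
        for j in range(J):
            k = i * J + j
            if i + 1 < I:
                cons.append({"type": "ineq", "fun": lambda x, a=k, b=k + J: x[b] - x[a]})
            if j + 1 < J:
                cons.append({"type": "ineq", "fun": lambda x, a=k, b=k + 1: x[b] - x[a]})
    w = weights.ravel()
    v = values.ravel()
    res = minimize(
        lambda x: np.sum(w * (x - v) ** 2),
        x0=np.full(v.size, v.mean()),
        jac=lambda x: 2 * w * (x - v),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success
    return res.x.reshape(I, J)


class TestMatrixIsotonic:
    def test_monotone_input_is_fixed_point(self):
        x = np.array([[0.1, 0.2, 0.3], [0.2, 0.3, 0.4]])
        out = matrix_isotonic(x, np.ones_like(x))
        np.testing.assert_allclose(out, x, atol=1e-9)

    def test_pava_pair(self):
        out = matrix_isotonic(np.array([[0.5, 0.1]]), np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(out, [[0.3, 0.3]], atol=1e-9)

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3)])
    def test_matches_qp_oracle(self, shape, rng):
        # the exact weighted least-squares projection, via a generic solver
        for _ in range(50):
            vals = rng.uniform(0, 1, size=shape)
            wts = rng.uniform(0.2, 3.0, size=shape)
            ours = matrix_isotonic(vals, wts)
            oracle = _qp_isotonic_oracle(vals, wts)
            np.testing.assert_allclose(ours, oracle, atol=2e-6)

    def test_idempotent_and_mean_preserving(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 1, size=(3, 3))
            wts = rng.uniform(0.5, 2.0, size=(3, 3))
            out = matrix_isotonic(vals, wts)
            np.testing.assert_allclose(matrix_isotonic(out, wts), out, atol=1e-8)
            assert np.sum(wts * out) == pytest.approx(np.sum(wts * vals), rel=1e-8)
            assert np.all(np.diff(out, axis=0) >= -1e-10)
            assert np.all(np.diff(out, axis=1) >= -1e-10)

    def test_zero_weight_cells_filled_monotone(self):
        vals = np.array([[0.1, 0.0], [0.0, 0.4]])
        wts = np.array([[3.0, 0.0], [0.0, 3.0]])
        out = matrix_isotonic(vals, wts)
        assert out[0, 0] == pytest.approx(0.1, abs=1e-6)
        assert out[1, 1] == pytest.approx(0.4, abs=1e-6)
        assert np.all(np.diff(out, axis=0) >= -1e-10) and np.all(np.diff(out, axis=1) >= -1e-10)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            matrix_isotonic(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_isotonic_1d_weighted(self):
        out = isotonic_1d(np.array([0.6, 0.2]), np.array([1.0, 3.0]))
        np.testing.assert_allclose(out, [0.3, 0.3], atol=1e-12)


class TestSelectMtcIsotonic:
    def _state(self, n, y, grid=None):
        st = TrialState(grid or DoseGrid(*np.shape(n)))
        st.n = np.array(n, dtype=np.int64)
        st.y = np.array(y, dtype=np.int64)
        return st

    def test_single_tested_combination(self, rng):
        st = self._state([[3, 0], [0, 0]], [[1, 0], [0, 0]])
        assert select_mtc_isotonic(st, 0.30, rng) == (1, 1)

    def test_1x2_closest_to_target(self, rng):
        # isotonic estimates (0, 1/3); |1/3 - 0.3| < |0 - 0.3|
        st = self._state([[3, 3]], [[0, 1]])
        assert select_mtc_isotonic(st, 0.30, rng) == (1, 2)

    def test_stopped_trial_returns_none(self, rng):
        st = self._state([[3]], [[3]])
        st.stopped = True
        assert select_mtc_isotonic(st, 0.30, rng) is None

    def test_untested_never_selected(self, rng):
        st = self._state([[3, 0], [0, 0]], [[0, 0], [0, 0]])
        for _ in range(10):
            assert select_mtc_isotonic(st, 0.30, rng) == (1, 1)

    def test_tie_prefers_larger_n(self, rng):
        # both tested cells end equidistant from the target
        st = self._state([[6, 3]], [[1, 1]])  # rates 1/6, 1/3 -> isotonic keeps both
        pick = select_mtc_isotonic(st, 0.25, rng)
        assert pick == (1, 1) or pick == (1, 2)  # 1/6 vs 1/3 equidistant from 0.25
        counts = {c: 0 for c in [(1, 1), (1, 2)]}
        for k in range(50):
            counts[select_mtc_isotonic(st, 0.25, np.random.default_rng(k))] += 1
        assert counts[(1, 1)] == 50  # larger n wins the tie deterministically
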