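"""PIPE design: product of independent Beta probabilities escalation.

Each combination's toxicity gets an independent Beta prior; the design
estimates the MTC *contour* -- the monotone boundary separating combinations
believed safe (pi <= phi) from overly toxic ones.  Every monotone binary
matrix on the grid is a candidate contour (there are C(I+J, I) of them); the
posterior score of a contour is the product over cells of P(pi <= phi) or
P(pi > phi) according to the side the contour assigns.  Dosing randomises
over admissible combinations just below the modal contour, weighting towards
less-explored cells; the overdose rule averages the above-contour indicator
over the (normalised) contour posterior.

Prior construction follows the reference PIPE convention of matching the
prior *median* toxicity to the elicited value at each cell (with tiny prior
sample sizes a Beta distribution is bimodal, so mean-matching would put
almost all prior mass below any plausible target and the contour posterior
would be dominated by untested cells; median-matching leaves untested cells
close to non-informative for the contour).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb as binom

import numpy as np
from scipy.optimize import brentq
from scipy.special import betainc

from .designs import Design, TrialController, choose_max, choose_min_distance
from .grid import Comb, DoseGrid, TrialState, admissible_moves

__all__ = [
    "PipePrior",
    "pipe_build_prior",
    "enumerate_contours",
    "cell_below_prob",
    "contour_scores",
    "contour_posterior",
    "pipe_overdose_q",
    "closest_below",
    "PipeDesign",
]

MAX_GRID_CELLS = 20


@dataclass(frozen=True)
class PipePrior:
    """Independent Beta(a_ij, b_ij) priors for the toxicity matrix."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.shape != b.shape or np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("prior hyper-parameters must be positive and congruent")

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def medians(self) -> np.ndarray:
        out = np.empty_like(self.a)
        for idx in np.ndindex(self.a.shape):
            aa, bb = self.a[idx], self.b[idx]
            out[idx] = brentq(lambda x: betainc(aa, bb, x) - 0.5, 1e-12, 1 - 1e-12)
        return out


def _segment_levels(rho: float, delta: float, grid: DoseGrid) -> np.ndarray:
    I, J = grid.shape
    seg = np.add.outer(np.arange(I), np.arange(J))  # i+j-2 on 1-based indices
    levels = rho + seg * delta
    if np.any(levels >= 1):
        raise ValueError("prior toxicity levels must stay below 1; reduce rho or delta")
    return levels


def pipe_build_prior(
    rho: float,
    delta: float,
    s: float,
    grid: DoseGrid,
    parametrisation: str = "median",
) -> PipePrior:
    """Anti-diagonal segment prior with per-cell effective sample size s.

    The grid is divided into I+J-1 anti-diagonal segments (cells sharing
    i+j); the elicited prior toxicity rises by delta per segment from rho at
    the lowest combination, respecting monotonicity.  With
    ``parametrisation="median"`` (the default, matching the reference PIPE
    convention) the Beta(a, b) pair with a+b = s is solved so its median
    equals the elicited level; ``"mean"`` sets a = level*s, b = (1-level)*s
    directly.
    """
    if rho <= 0 or delta < 0 or s <= 0:
        raise ValueError("need rho > 0, delta >= 0, s > 0")
    levels = _segment_levels(rho, delta, grid)
    if parametrisation == "mean":
        return PipePrior(levels * s, (1.0 - levels) * s)
    if parametrisation != "median":
        raise ValueError("parametrisation must be 'median' or 'mean'")
    a = np.empty_like(levels)
    for idx in np.ndindex(levels.shape):
        med = levels[idx]
        a[idx] = brentq(lambda x: betainc(x, s - x, med) - 0.5, 1e-12 * s, s * (1 - 1e-12))
    return PipePrior(a, s - a)


@lru_cache(maxsize=None)
def _contours_cached(I: int, J: int) -> np.ndarray:
    rows: list[tuple[int, ...]] = []

    def rec(prefix: list[int]) -> None:
        if len(prefix) == I:
            rows.append(tuple(prefix))
            return
        lo = prefix[-1] if prefix else 0
        for k in range(lo, J + 1):
            rec(prefix + [k])

    rec([])
    out = np.zeros((len(rows), I, J), dtype=np.int8)
    for s, ks in enumerate(rows):
        for i, k in enumerate(ks):
            if k:
                out[s, i, J - k :] = 1
    # lexicographic order on the flattened binary cells, deterministic
    order = np.lexsort(out.reshape(len(rows), -1).T[::-1])
    return out[order]


def enumerate_contours(grid: DoseGrid) -> np.ndarray:
    """All monotone binary matrices on the grid, shape (C(I+J, I), I, J).

    Entry 1 marks a cell above the contour (believed overly toxic); the 1-set
    is an upper set of the grid's partial order, so each contour is a
    non-decreasing 0/1 matrix in both indices.
    """
    I, J = grid.shape
    if I * J > MAX_GRID_CELLS:
        raise ValueError(f"grid with {I * J} cells exceeds the {MAX_GRID_CELLS}-cell contour guard")
    out = _contours_cached(I, J)
    assert out.shape[0] == binom(I + J, I)
    return out


def cell_below_prob(state: TrialState, prior: PipePrior, target: float) -> np.ndarray:
    """p_ij = P(pi_ij <= target) under the Beta posterior at each cell."""
    a = prior.a + state.y
    b = prior.b + state.n - state.y
    return betainc(a, b, target)


def contour_scores(p: np.ndarray, contours: np.ndarray) -> np.ndarray:
    """Unnormalised posterior score of each contour given the p_ij matrix."""
    flat_p = p.reshape(-1)
    flat_c = contours.reshape(contours.shape[0], -1)
    return np.prod(np.where(flat_c == 1, 1.0 - flat_p, flat_p), axis=1)


def contour_posterior(p: np.ndarray, contour: np.ndarray) -> float:
    """Posterior score of a single contour (product over cells)."""
    return float(np.prod(np.where(contour == 1, 1.0 - p, p)))


def pipe_overdose_q(p: np.ndarray, contours: np.ndarray) -> np.ndarray:
    """q_ij: expected above-contour indicator under the contour posterior.

    Contour scores are normalised to a proper distribution over the monotone
    contours before averaging, so q_ij is a genuine posterior expectation.
    """
    scores = contour_scores(p, contours)
    w = scores / scores.sum()
    return np.tensordot(w, contours.astype(float), axes=(0, 0))


@lru_cache(maxsize=32)
def _below_prob_table(
    target: float, rho: float, delta: float, s: float, shape: tuple[int, int], nmax: int
) -> np.ndarray:
    """p_ij = P(pi <= target | y, n) for every cell and count pair (n, y)."""
    prior = pipe_build_prior(rho, delta, s, DoseGrid(*shape))
    n = np.arange(nmax + 1)[:, None, None, None]
    y = np.arange(nmax + 1)[None, :, None, None]
    a = prior.a[None, None] + y
    b = prior.b[None, None] + np.maximum(n - y, 0)
    return np.where(y <= n, betainc(a, b, target), np.nan)


def _contour_distance(contour: np.ndarray) -> np.ndarray:
    """Lattice distance from each below-contour cell to the boundary.

    For a 0-cell the distance is the least number of single-level increases
    needed to reach an above-contour cell or leave the grid; above-contour
    cells get distance 0.  Cells at distance 1 are the classic "adjacent to
    the contour from below" set.
    """
    I, J = contour.shape
    d = np.zeros((I, J), dtype=np.int64)
    for i in range(I - 1, -1, -1):
        for j in range(J - 1, -1, -1):
            if contour[i, j] == 1:
                d[i, j] = 0
                continue
            up = d[i + 1, j] + 1 if i + 1 < I else 1
            right = d[i, j + 1] + 1 if j + 1 < J else 1
            d[i, j] = min(up, right)
    return d


def closest_below(contour: np.ndarray) -> list[Comb]:
    """Below-contour cells adjacent to the contour boundary (recommendation set).

    With at least one above-contour cell these are the 0-cells with an
    orthogonal above-contour neighbour; for the all-safe contour they are the
    cells on the grid's upper-right boundary.
    """
    I, J = contour.shape
    out = []
    any_one = bool(contour.any())
    for i in range(I):
        for j in range(J):
            if contour[i, j] == 1:
                continue
            if any_one:
                if (i + 1 < I and contour[i + 1, j] == 1) or (j + 1 < J and contour[i, j + 1] == 1):
                    out.append((i + 1, j + 1))
            elif i == I - 1 or j == J - 1:
                out.append((i + 1, j + 1))
    return out


@dataclass(frozen=True)
class PipeDesign(Design):
    """Calibrated PIPE configuration."""

    target: float = 0.30
    rho: float = 0.05
    delta: float = 0.025
    s: float = 1.0 / 18.0
    epsilon: float = 0.50

    name = "pipe"

    def new_trial(self, grid: DoseGrid) -> "_PipeController":
        return _PipeController(self, grid)

    def prior(self, grid: DoseGrid) -> PipePrior:
        return pipe_build_prior(self.rho, self.delta, self.s, grid)


class _PipeController(TrialController):
    """Per-trial PIPE logic.

    The overdose rule is evidence-based and transient: a *tested* cell with
    q_ij >= epsilon cannot receive the next cohort (the set is re-derived
    from the current contour posterior before every allocation, mirroring
    how the BOIN-type rules require observed data before acting); the trial
    terminates when the lowest combination is barred.
    """

    _P_TABLE_N = 36  # lookup depth: posterior p for all (n, y) up to the budget

    def __init__(self, cfg: PipeDesign, grid: DoseGrid) -> None:
        self.cfg = cfg
        self.grid = grid
        self.prior = cfg.prior(grid)
        self.contours = enumerate_contours(grid)
        self._best_contour: np.ndarray | None = None
        self._p_table = _below_prob_table(
            cfg.target, cfg.rho, cfg.delta, cfg.s, grid.shape, self._P_TABLE_N
        )

    def _update_contour(self, state: TrialState) -> np.ndarray:
        if state.n.max(initial=0) <= self._P_TABLE_N:
            p = self._p_table[state.n, state.y, np.arange(state.n.shape[0])[:, None],
                              np.arange(state.n.shape[1])[None, :]]
        else:
            p = cell_below_prob(state, self.prior, self.cfg.target)
        scores = contour_scores(p, self.contours)
        best = int(np.argmax(scores))  # lowest enumeration index wins exact ties
        self._best_contour = self.contours[best]
        self._p = p
        self._q = np.tensordot(scores / scores.sum(), self.contours.astype(float), axes=(0, 0))
        return self._best_contour

    def next_combination(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        contour = self._update_contour(state)
        if self.cfg.epsilon < 1.0:
            blocked = {
                (i + 1, j + 1)
                for i, j in zip(*np.nonzero((self._q >= self.cfg.epsilon) & (state.n > 0)))
            }
            state.eliminated = blocked
            if (1, 1) in blocked:
                state.stopped = True
                return None
        admissible = admissible_moves(state.current, "extended", self.grid, state.eliminated)
        if not admissible:
            state.stopped = True
            return None
        below = [c for c in admissible if contour[c[0] - 1, c[1] - 1] == 0]
        if below:
            # candidates: admissible below-contour cells nearest the boundary
            dist = _contour_distance(contour)
            dmin = min(dist[c[0] - 1, c[1] - 1] for c in below)
            cands = [c for c in below if dist[c[0] - 1, c[1] - 1] == dmin]
            weights = np.array([1.0 / (state.n[c[0] - 1, c[1] - 1] + 1) for c in cands])
            nxt = cands[int(rng.choice(len(cands), p=weights / weights.sum()))]
        else:
            # every admissible cell sits above the modal contour: fall back to
            # the least decisively classified admissible cell
            nxt = choose_max(
                sorted(admissible),
                {c: -abs(self._p[c[0] - 1, c[1] - 1] - 0.5) for c in admissible},
                rng,
            )
        state.current = nxt
        return nxt

    def recommend(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        """Single MTC from the final modal contour.

        Recommendable cells are the tested closest-from-below combinations;
        among them the ones whose posterior-mean toxicity does not exceed
        the target (i.e. genuinely believed below the contour) are preferred,
        and the posterior mean closest to the target wins.
        """
        if state.stopped:
            return None
        contour = self._update_contour(state)
        cands = [c for c in closest_below(contour) if state.n[c[0] - 1, c[1] - 1] > 0]
        if not cands:
            return None
        post_mean = (self.prior.a + state.y) / (self.prior.a + self.prior.b + state.n)
        safe = [c for c in cands if post_mean[c[0] - 1, c[1] - 1] <= self.cfg.target + 1e-12]
        if safe:
            cands = safe
        est = {c: float(post_mean[c[0] - 1, c[1] - 1]) for c in cands}
        return choose_min_distance(cands, est, self.cfg.target, rng)
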