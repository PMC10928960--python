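"""Dose-grid geometry, trial bookkeeping and shared estimation primitives.

The dual-agent dose grid has ``I`` ordered levels of drug A (rows) and ``J``
ordered levels of drug B (columns).  Combinations are addressed with 1-based
pairs ``(i, j)`` throughout, matching the d_ij convention used in the
dose-finding literature; the underlying matrices are 0-based numpy arrays.

This module houses the pieces every design shares: admissible one-step moves,
conjugate Beta updating of per-combination toxicity probabilities, and the
2-D (bimonotone) matrix isotonic regression used for final MTC selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc

Comb = tuple[int, int]

__all__ = [
    "DoseGrid",
    "BetaParams",
    "TrialState",
    "admissible_moves",
    "posterior_beta",
    "beta_tail_prob",
    "isotonic_1d",
    "matrix_isotonic",
    "select_mtc_isotonic",
]


@dataclass(frozen=True)
class DoseGrid:
    """An I x J grid of dose combinations, 1-based indexing."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one level of each drug")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def contains(self, comb: Comb) -> bool:
        i, j = comb
        return 1 <= i <= self.n_rows and 1 <= j <= self.n_cols

    def validate(self, comb: Comb) -> None:
        if not self.contains(comb):
            raise IndexError(f"combination {comb} outside {self.n_rows}x{self.n_cols} grid")

    def combinations(self) -> list[Comb]:
        return [(i, j) for i in range(1, self.n_rows + 1) for j in range(1, self.n_cols + 1)]


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class TrialState:
    """Mutable per-trial bookkeeping: patient counts, DLT counts, position.

    ``n[i-1, j-1]`` patients have been treated at combination ``(i, j)`` and
    ``y[i-1, j-1]`` of them experienced a dose-limiting toxicity.
    """

    grid: DoseGrid
    n: np.ndarray = field(init=False)
    y: np.ndarray = field(init=False)
    current: Comb = (1, 1)
    eliminated: set[Comb] = field(default_factory=set)
    stopped: bool = False
    cohort_log: list[tuple[Comb, tuple[int, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n = np.zeros(self.grid.shape, dtype=np.int64)
        self.y = np.zeros(self.grid.shape, dtype=np.int64)

    def record_cohort(self, comb: Comb, responses: tuple[int, ...] | list[int]) -> None:
        self.grid.validate(comb)
        responses = tuple(int(r) for r in responses)
        if any(r not in (0, 1) for r in responses):
            raise ValueError("responses must be binary")
        i, j = comb
        self.n[i - 1, j - 1] += len(responses)
        self.y[i - 1, j - 1] += sum(responses)
        self.cohort_log.append((comb, responses))

    def counts(self, comb: Comb) -> tuple[int, int]:
        i, j = comb
        return int(self.y[i - 1, j - 1]), int(self.n[i - 1, j - 1])

    def tested(self) -> list[Comb]:
        return [c for c in self.grid.combinations() if self.n[c[0] - 1, c[1] - 1] > 0]

    @property
    def n_patients(self) -> int:
        return int(self.n.sum())


def admissible_moves(
    current: Comb,
    family: str,
    grid: DoseGrid,
    eliminated: set[Comb] | frozenset[Comb] = frozenset(),
) -> set[Comb]:
    """Combinations the next cohort may receive from ``current``.

    ``family="orthogonal"`` (BOIN, Keyboard, Waterfall): the current
    combination plus single-drug escalation/de-escalation.
    ``family="extended"`` (Surface-Free, PIPE): additionally diagonal
    de-escalation ``(i-1, j-1)`` and anti-diagonal moves ``(i+1, j-1)``,
    ``(i-1, j+1)``.  Simultaneous escalation of both drugs ``(i+1, j+1)``
    is never admissible, and no dose level can be skipped.
    """
    grid.validate(current)
    if family not in ("orthogonal", "extended"):
        raise ValueError(f"unknown move family {family!r}")
    i, j = current
    steps = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
    if family == "extended":
        steps += [(-1, -1), (1, -1), (-1, 1)]
    moves = {(i + di, j + dj) for di, dj in steps}
    return {c for c in moves if grid.contains(c) and c not in eliminated}


def posterior_beta(y: int, n: int, prior: BetaParams) -> BetaParams:
    """Conjugate Beta update for ``y`` DLTs among ``n`` binomial patients."""
    if n < 0 or y < 0 or y > n:
        raise ValueError(f"invalid counts y={y}, n={n}")
    return BetaParams(prior.alpha + y, prior.beta + n - y)


def beta_tail_prob(params: BetaParams, threshold: float) -> float:
    """P(pi > threshold) under a Beta distribution."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return float(1.0 - betainc(params.alpha, params.beta, threshold))


def isotonic_1d(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted non-decreasing least-squares fit (pool-adjacent-violators)."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    # stack of (level, weight) blocks
    levels: list[float] = []
    wts: list[float] = []
    sizes: list[int] = []
    for v, wi in zip(x, w):
        levels.append(v)
        wts.append(wi)
        sizes.append(1)
        while len(levels) > 1 and levels[-2] >= levels[-1]:
            v2, w2, s2 = levels.pop(), wts.pop(), sizes.pop()
            v1, w1, s1 = levels.pop(), wts.pop(), sizes.pop()
            wt = w1 + w2
            levels.append((v1 * w1 + v2 * w2) / wt if wt > 0 else min(v1, v2))
            wts.append(wt)
            sizes.append(s1 + s2)
    out = np.empty_like(x)
    pos = 0
    for v, s in zip(levels, sizes):
        out[pos : pos + s] = v
        pos += s
    return out


_W_FLOOR = 1e-8  # pseudo-weight for untested cells: monotone fill, negligible pull


def matrix_isotonic(
    values: np.ndarray,
    weights: np.ndarray,
    tol: float = 1e-10,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Weighted least-squares projection onto the bimonotone cone.

    Returns the matrix non-decreasing along rows and columns that minimises
    the weighted squared distance to ``values``.  Computed by Dykstra's
    alternating projections, with a row pool-adjacent-violators pass and a
    column pass per sweep; with the Dykstra correction terms the iteration
    converges to the exact projection (plain cyclic PAVA only reaches a
    feasible point).  Zero-weight cells (untested combinations) receive a
    tiny pseudo-weight so they are filled by monotone extension without
    influencing the projection of the tested cells.
    """
    x0 = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x0.shape != w.shape:
        raise ValueError("values and weights must have the same shape")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("at least one cell must have positive weight")
    w = np.where(w > 0, w, _W_FLOOR * w[w > 0].min())

    x = x0.copy()
    p = np.zeros_like(x)  # Dykstra increment, row constraint
    q = np.zeros_like(x)  # Dykstra increment, column constraint
    for _ in range(max_sweeps):
        z = x + p
        y = np.vstack([isotonic_1d(z[r], w[r]) for r in range(z.shape[0])])
        p = z - y
        z = y + q
        x_new = np.column_stack(
            [isotonic_1d(z[:, c], w[:, c]) for c in range(z.shape[1])]
        )
        q = z - x_new
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return x


def select_mtc_isotonic(
    state: TrialState,
    target: float,
    rng: np.random.Generator | None = None,
    exclude: set[Comb] | frozenset[Comb] = frozenset(),
) -> Comb | None:
    """Final MTC pick: isotonic estimates, tested combination closest to target.

    Empirical DLT rates are projected onto the bimonotone cone with the
    patient counts as weights; only combinations that actually treated
    patients (and are not in ``exclude``) are eligible.  Ties on the distance
    to the target prefer the better-characterised combination (larger n),
    then fall to a uniform random draw.
    """
    if state.stopped:
        return None
    eligible = [c for c in state.tested() if c not in exclude]
    if not eligible:
        return None
    n = state.n.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(n > 0, state.y / np.maximum(n, 1), 0.0)
    est = matrix_isotonic(rates, n)
    dist = {c: abs(est[c[0] - 1, c[1] - 1] - target) for c in eligible}
    best = min(dist.values())
    ties = [c for c in eligible if dist[c] <= best + 1e-12]
    if len(ties) == 1:
        return ties[0]
    nmax = max(state.n[c[0] - 1, c[1] - 1] for c in ties)
    ties = [c for c in ties if state.n[c[0] - 1, c[1] - 1] == nmax]
    if len(ties) == 1:
        return ties[0]
    rng = rng if rng is not None else np.random.default_rng()
    return ties[int(rng.integers(len(ties)))]
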