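"""BOIN and Keyboard designs for dual-agent escalation.

Both designs treat the combinations independently under vague Beta(1,1)
priors and compare the evidence at the current combination against a fixed
interval around the target toxicity phi.  BOIN compares the raw empirical
DLT rate with optimal boundaries (lambda_e, lambda_d); Keyboard tiles (0,1)
into equal-width "keys" and compares the posterior-modal key with the target
key.  Both share the Beta-posterior overdose rule: a tested combination with
P(pi > phi | data) >= epsilon is eliminated together with every combination
higher in either drug, and the trial stops if the lowest combination is
eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from math import log

import numpy as np
from scipy.special import betainc

from .designs import Design, TrialController, choose_max
from .grid import Comb, DoseGrid, TrialState, select_mtc_isotonic

__all__ = [
    "BoinConfig",
    "KeyConfig",
    "KeyPartition",
    "boin_thresholds",
    "key_partition",
    "interval_overdose_update",
]

MAX_N = 36  # decision tables cover up to the full trial sample size


def boin_thresholds(target: float, phi1: float, phi2: float) -> tuple[float, float]:
    """Optimal escalation/de-escalation boundaries (lambda_e, lambda_d).

    phi1 is the highest sub-therapeutic toxicity, phi2 the lowest overly
    toxic one; the boundaries minimise the local probability of an incorrect
    escalation decision and depend only on (target, phi1, phi2).
    """
    if not 0 < phi1 < target < phi2 < 1:
        raise ValueError("need 0 < phi1 < target < phi2 < 1")
    lam_e = log((1 - phi1) / (1 - target)) / log(target * (1 - phi1) / (phi1 * (1 - target)))
    lam_d = log((1 - target) / (1 - phi2)) / log(phi2 * (1 - target) / (target * (1 - phi2)))
    return lam_e, lam_d


def _posterior_interval_table(lo: float, hi: float, n_max: int = MAX_N) -> np.ndarray:
    """table[n, y] = P(pi in (lo, hi) | Beta(y+1, n-y+1)); nan where y > n."""
    n = np.arange(n_max + 1)[:, None]
    y = np.arange(n_max + 1)[None, :]
    a = y + 1.0
    b = np.maximum(n - y, 0) + 1.0
    t = betainc(a, b, hi) - betainc(a, b, lo)
    return np.where(y <= n, t, np.nan)


def _posterior_tail_table(threshold: float, n_max: int = MAX_N) -> np.ndarray:
    """table[n, y] = P(pi > threshold | Beta(y+1, n-y+1))."""
    n = np.arange(n_max + 1)[:, None]
    y = np.arange(n_max + 1)[None, :]
    a = y + 1.0
    b = np.maximum(n - y, 0) + 1.0
    return np.where(y <= n, 1.0 - betainc(a, b, threshold), np.nan)


def interval_overdose_update(
    state: TrialState,
    target: float,
    epsilon: float,
    tail_table: np.ndarray | None = None,
) -> None:
    """Eliminate combinations breaching the Beta-posterior overdose rule.

    Any tested combination with P(pi > target | y, n) >= epsilon is added to
    ``state.eliminated`` together with its whole upper orthant (every
    combination at least as high in both drugs), the only set guaranteed more
    toxic under monotonicity.  epsilon = 1 disables the rule entirely; if
    (1,1) is eliminated the trial stops with no recommendation.
    """
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    if epsilon >= 1.0:
        return
    if tail_table is None:
        tail_table = _posterior_tail_table(target, int(state.n.max(initial=0)))
    I, J = state.grid.shape
    for i in range(1, I + 1):
        for j in range(1, J + 1):
            nij = int(state.n[i - 1, j - 1])
            if nij == 0 or (i, j) in state.eliminated:
                continue
            if tail_table[nij, int(state.y[i - 1, j - 1])] >= epsilon:
                for i2 in range(i, I + 1):
                    for j2 in range(j, J + 1):
                        state.eliminated.add((i2, j2))
    if (1, 1) in state.eliminated:
        state.stopped = True


@dataclass(frozen=True)
class BoinConfig(Design):
    """BOIN configuration: phi1 = a1*target, phi2 = a2*target."""

    target: float = 0.30
    a1: float = 0.65
    a2: float = 1.40
    epsilon: float = 0.84

    name = "boin"

    def __post_init__(self) -> None:
        if not 0 < self.a1 < 1 < self.a2:
            raise ValueError("need 0 < a1 < 1 < a2")
        if not 0 < self.a2 * self.target < 1:
            raise ValueError("phi2 must lie below 1")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")

    @cached_property
    def thresholds(self) -> tuple[float, float]:
        return boin_thresholds(self.target, self.a1 * self.target, self.a2 * self.target)

    @cached_property
    def _interval_table(self) -> np.ndarray:
        return _posterior_interval_table(*self.thresholds)

    @cached_property
    def _tail_table(self) -> np.ndarray:
        return _posterior_tail_table(self.target)

    def new_trial(self, grid: DoseGrid) -> "_IntervalController":
        return _IntervalController(self, grid)

    # direction of the next move given the data at the current combination:
    # +1 escalate, 0 stay, -1 de-escalate
    def direction(self, y: int, n: int) -> int:
        lam_e, lam_d = self.thresholds
        phat = y / n
        if phat <= lam_e + 1e-12:
            return 1
        if phat > lam_d + 1e-12:
            return -1
        return 0

    def within_set_score(self, y: int, n: int) -> float:
        return float(self._interval_table[n, y])


@dataclass(frozen=True)
class KeyPartition:
    """Tiling of (0,1) into keys of equal width (shorter at the edges)."""

    edges: tuple[float, ...]
    target_index: int

    @property
    def keys(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))

    @property
    def target_key(self) -> tuple[float, float]:
        return self.keys[self.target_index]


def key_partition(b1: float, b2: float) -> KeyPartition:
    """Tile (0,1) with keys of width b2-b1 stepping outward from (b1, b2)."""
    if not 0 < b1 < b2 < 1:
        raise ValueError("need 0 < b1 < b2 < 1")
    width = b2 - b1
    edges = [b1, b2]
    while edges[0] > 1e-12:
        edges.insert(0, max(edges[0] - width, 0.0))
    while edges[-1] < 1 - 1e-12:
        edges.append(min(edges[-1] + width, 1.0))
    edges[0], edges[-1] = 0.0, 1.0
    return KeyPartition(tuple(edges), edges.index(b1))


@dataclass(frozen=True)
class KeyConfig(Design):
    """Keyboard configuration: target key (b1, b2) containing the target."""

    target: float = 0.30
    b1: float = 0.21
    b2: float = 0.39
    epsilon: float = 0.84

    name = "keyboard"

    def __post_init__(self) -> None:
        if not self.b1 < self.target < self.b2:
            raise ValueError("target key must contain the target toxicity")

    @cached_property
    def partition(self) -> KeyPartition:
        return key_partition(self.b1, self.b2)

    @cached_property
    def _target_mass_table(self) -> np.ndarray:
        return _posterior_interval_table(self.b1, self.b2)

    @cached_property
    def _tail_table(self) -> np.ndarray:
        return _posterior_tail_table(self.target)

    @cached_property
    def _imax_table(self) -> np.ndarray:
        """imax[n, y] = index of the posterior-modal key under Beta(y+1, n-y+1).

        Exact posterior-mass ties between keys (possible only with symmetric
        edge keys) are broken toward the key nearest the target, i.e. toward
        staying, the conservative reading.
        """
        part = self.partition
        edges = np.array(part.edges)
        n_max = MAX_N
        tbl = np.zeros((n_max + 1, n_max + 1), dtype=np.int64)
        for n in range(n_max + 1):
            ys = np.arange(n + 1)
            a = (ys + 1.0)[:, None]
            b = (n - ys + 1.0)[:, None]
            cdf = betainc(a, b, edges[None, :])
            masses = np.diff(cdf, axis=1)
            mx = masses.max(axis=1, keepdims=True)
            for k, row in enumerate(masses):
                tied = np.nonzero(row >= mx[k, 0] - 1e-15)[0]
                tbl[n, k] = tied[np.argmin(np.abs(tied - part.target_index))]
        return tbl

    def new_trial(self, grid: DoseGrid) -> "_IntervalController":
        return _IntervalController(self, grid)

    def direction(self, y: int, n: int) -> int:
        imax = int(self._imax_table[n, y])
        if imax < self.partition.target_index:
            return 1
        if imax > self.partition.target_index:
            return -1
        return 0

    def within_set_score(self, y: int, n: int) -> float:
        return float(self._target_mass_table[n, y])


class _IntervalController(TrialController):
    """Shared escalation machinery for the BOIN and Keyboard designs."""

    def __init__(self, cfg: BoinConfig | KeyConfig, grid: DoseGrid) -> None:
        self.cfg = cfg
        self.grid = grid

    def _score(self, state: TrialState, comb: Comb) -> float:
        y, n = state.counts(comb)
        return self.cfg.within_set_score(y, n)  # Beta(1,1) prior when untested

    def _pick(self, state: TrialState, cands: list[Comb], rng: np.random.Generator) -> Comb:
        return choose_max(cands, {c: self._score(state, c) for c in cands}, rng)

    def next_combination(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        interval_overdose_update(state, self.cfg.target, self.cfg.epsilon, self.cfg._tail_table)
        if state.stopped:
            return None
        i, j = state.current
        y, n = state.counts(state.current)
        if n == 0:
            raise RuntimeError("decision requested before any cohort at the current combination")
        if state.current in state.eliminated:
            # overdose rule just removed the current combination: de-escalate
            down = [c for c in ((i - 1, j), (i, j - 1))
                    if self.grid.contains(c) and c not in state.eliminated]
            if not down:
                state.stopped = True
                return None
            nxt = self._pick(state, down, rng)
        else:
            direction = self.cfg.direction(y, n)
            if direction == 0:
                nxt = state.current
            else:
                if direction > 0:
                    cands = [(i + 1, j), (i, j + 1)]
                else:
                    cands = [(i - 1, j), (i, j - 1)]
                cands = [c for c in cands if self.grid.contains(c) and c not in state.eliminated]
                nxt = self._pick(state, cands, rng) if cands else state.current
        state.current = nxt
        return nxt

    def recommend(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        if state.stopped:
            return None
        return select_mtc_isotonic(state, self.cfg.target, rng, exclude=state.eliminated)
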