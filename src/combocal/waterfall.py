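"""Waterfall design: sequential one-dimensional sub-trials.

The I x J grid is split into I sub-trials run with the single-agent BOIN
rule: S_I climbs the first column then across the top row
((1,1),...,(I,1),(I,2),...,(I,J)); each S_k for k < I covers row k from
column 2 ((k,2),...,(k,J)).  Each sub-trial ends when its cohort budget is
spent, yielding a "candidate MTD" by isotonic regression over its doses; a
candidate at row i* hands off to sub-trial S_{i*-1}, which starts one drug-B
level above the candidate's column (clipped into the sub-trial's range).
After the last sub-trial, matrix isotonic regression over all collated data
selects the best dose per row (the recommended contour), reduced to a single
MTC by the posterior mean under Beta(1,1).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .designs import Design, TrialController, choose_min_distance
from .grid import Comb, DoseGrid, TrialState, isotonic_1d, matrix_isotonic
from .interval import BoinConfig, interval_overdose_update

__all__ = ["SubtrialPlan", "partition_subtrials", "default_cohort_split", "WaterfallDesign"]


@dataclass(frozen=True)
class SubtrialPlan:
    """Ordered sub-trial sequences S_I ... S_1 (disjoint cover of the grid)."""

    subtrials: tuple[tuple[Comb, ...], ...]

    def __len__(self) -> int:
        return len(self.subtrials)


def partition_subtrials(grid: DoseGrid) -> SubtrialPlan:
    I, J = grid.shape
    first = tuple((i, 1) for i in range(1, I + 1)) + tuple((I, j) for j in range(2, J + 1))
    rest = tuple(tuple((k, j) for j in range(2, J + 1)) for k in range(I - 1, 0, -1))
    rest = tuple(seq for seq in rest if seq)
    return SubtrialPlan((first,) + rest)


def default_cohort_split(grid: DoseGrid, n_cohorts: int = 12) -> tuple[int, ...]:
    """Cohort allocation across sub-trials: 6/3/3 on 3x3 grids, 8/4 on 2xJ.

    The long first sub-trial receives twice the budget of each later one
    (2n/(k+1) cohorts for k sub-trials), which reproduces both reference
    splits; any integer remainder goes to the first sub-trial.
    """
    plan = partition_subtrials(grid)
    k = len(plan)
    if k == 1:
        return (n_cohorts,)
    first = (2 * n_cohorts) // (k + 1)
    later = first // 2
    first += n_cohorts - first - later * (k - 1)
    return (first,) + (later,) * (k - 1)


@dataclass(frozen=True)
class WaterfallDesign(Design):
    """Waterfall configuration; escalation parameters shared with BOIN."""

    target: float = 0.30
    a1: float = 0.65
    a2: float = 1.40
    epsilon: float = 0.84
    cohort_split: tuple[int, ...] | None = None  # None: default split for the grid

    name = "waterfall"

    @cached_property
    def boin(self) -> BoinConfig:
        return BoinConfig(self.target, self.a1, self.a2, self.epsilon)

    def new_trial(self, grid: DoseGrid) -> "_WaterfallController":
        return _WaterfallController(self, grid)


class _WaterfallController(TrialController):
    def __init__(self, cfg: WaterfallDesign, grid: DoseGrid) -> None:
        self.cfg = cfg
        self.grid = grid
        self.plan = partition_subtrials(grid)
        split = cfg.cohort_split or default_cohort_split(grid)
        if len(split) != len(self.plan):
            raise ValueError("cohort_split length must match the number of sub-trials")
        self.split = tuple(split)
        self.sub_idx = 0  # position in plan order (0 = S_I)
        self.cohorts_in_sub = 0
        self.done = False

    # ---- single-agent BOIN step along the active sequence ----------------

    def _sequence(self) -> tuple[Comb, ...]:
        return self.plan.subtrials[self.sub_idx]

    def _candidate_mtd(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        """Isotonic selection over the sub-trial's tested, non-eliminated doses."""
        seq = self._sequence()
        tested = [c for c in seq if state.n[c[0] - 1, c[1] - 1] > 0 and c not in state.eliminated]
        if not tested:
            return None
        wts = np.array([state.n[c[0] - 1, c[1] - 1] for c in seq], dtype=float)
        vals = np.array(
            [state.y[c[0] - 1, c[1] - 1] / max(state.n[c[0] - 1, c[1] - 1], 1) for c in seq]
        )
        wts = np.where(wts > 0, wts, 1e-8)
        est = isotonic_1d(vals, wts)
        by_comb = {c: float(est[k]) for k, c in enumerate(seq)}
        dist = {c: abs(by_comb[c] - self.cfg.target) for c in tested}
        best = min(dist.values())
        ties = [c for c in tested if dist[c] <= best + 1e-12]
        nmax = max(state.n[c[0] - 1, c[1] - 1] for c in ties)
        ties = [c for c in ties if state.n[c[0] - 1, c[1] - 1] == nmax]
        return ties[0] if len(ties) == 1 else ties[int(rng.integers(len(ties)))]

    def _advance_subtrial(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        """Close the active sub-trial and open the next; returns its start dose."""
        candidate = self._candidate_mtd(state, rng)
        if candidate is None:
            # every dose of the sub-trial eliminated: candidate falls below
            # the sequence start (row unchanged, column 1)
            candidate = (self._sequence()[0][0], 1)
        i_star, j_star = candidate
        next_row = i_star - 1
        if next_row < 1:
            self.done = True
            return None
        # plan index of S_{next_row}: plan order is S_I, S_{I-1}, ..., S_1
        target_idx = len(self.plan) - next_row
        if target_idx <= self.sub_idx:
            self.done = True
            return None
        self.sub_idx = target_idx
        self.cohorts_in_sub = 0
        seq = self._sequence()
        cols = [c[1] for c in seq]
        start = (next_row, min(max(j_star + 1, min(cols)), max(cols)))
        live = [c for c in seq if c not in state.eliminated]
        if not live:
            return self._advance_subtrial_after_empty(state, rng)
        if start in state.eliminated:
            lower = [c for c in live if c[1] < start[1]]
            start = lower[-1] if lower else live[0]
        return start

    def _advance_subtrial_after_empty(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        # newly opened sub-trial has no administrable dose: forfeit it
        return self._advance_subtrial(state, rng)

    def next_combination(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        interval_overdose_update(state, self.cfg.target, self.cfg.epsilon, self.cfg.boin._tail_table)
        if state.stopped:
            return None
        self.cohorts_in_sub += 1
        seq = self._sequence()
        pos = seq.index(state.current)
        if self.cohorts_in_sub >= self.split[self.sub_idx]:
            nxt = self._advance_subtrial(state, rng)
            if nxt is None:
                return None  # all sub-trials complete (budget forfeited if early)
            state.current = nxt
            return nxt
        y, n = state.counts(state.current)
        direction = self.cfg.boin.direction(y, n)
        if state.current in state.eliminated:
            direction = -1
        nxt = state.current
        if direction > 0 and pos + 1 < len(seq) and seq[pos + 1] not in state.eliminated:
            nxt = seq[pos + 1]
        elif direction < 0:
            lower = [c for c in seq[:pos] if c not in state.eliminated]
            if lower:
                nxt = lower[-1]
            elif state.current in state.eliminated:
                # nothing administrable below in this sub-trial: close it early
                nxt = self._advance_subtrial(state, rng)
                if nxt is None:
                    return None
        state.current = nxt
        return nxt

    # ---- final contour and single-MTC reduction --------------------------

    def recommend(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        if state.stopped:
            return None
        tested = state.tested()
        if not tested:
            return None
        n = state.n.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(n > 0, state.y / np.maximum(n, 1), 0.0)
        est = matrix_isotonic(rates, n)
        contour: list[Comb] = []
        for i in range(1, self.grid.n_rows + 1):
            row_cands = [
                c for c in tested if c[0] == i and c not in state.eliminated
            ]
            if not row_cands:
                continue  # row untested or entirely overly toxic
            dist = {c: abs(est[c[0] - 1, c[1] - 1] - self.cfg.target) for c in row_cands}
            best = min(dist.values())
            ties = [c for c in row_cands if dist[c] <= best + 1e-12]
            nmax = max(state.n[c[0] - 1, c[1] - 1] for c in ties)
            ties = [c for c in ties if state.n[c[0] - 1, c[1] - 1] == nmax]
            contour.append(ties[0] if len(ties) == 1 else ties[int(rng.integers(len(ties)))])
        if not contour:
            return None
        post_mean = {
            c: (state.y[c[0] - 1, c[1] - 1] + 1.0) / (state.n[c[0] - 1, c[1] - 1] + 2.0)
            for c in contour
        }
        return choose_min_distance(contour, post_mean, self.cfg.target, rng)
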