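"""Deterministic replay of the neratinib + temsirolimus combination trial.

The observed counts from the dose-escalation study (restricted to a 3x3
grid: neratinib 120/160/200 mg by temsirolimus 25/50/75 mg, dropping the
lowest temsirolimus and highest neratinib levels) are turned into a fixed
bank of 36 ordered patient responses per combination.  The first n_ij
entries are a seed-fixed permutation of the observed responses; the
remainder are Bernoulli draws whose per-patient DLT probability comes from
Beta(1 + y_ij, 1 + n_ij - y_ij), or Beta(3, 3) for combinations the real
trial never used (flat-but-wary, since non-escalation usually signals a
safety concern).  Replaying every design against the same bank isolates the
escalation behaviour: any two designs that walk the same allocation path
see identical patient responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import Design
from .grid import Comb, DoseGrid, TrialState
from .simulate import DEFAULT_COHORT_SIZE, DEFAULT_N_COHORTS, TrialResult

__all__ = ["OBSERVED_N", "OBSERVED_Y", "ResponseBank", "build_response_bank", "replay", "allocation_table"]

# observed y/n counts on the restricted 3x3 grid of the motivating trial:
# rows neratinib 120/160/200 mg, columns temsirolimus 25/50/75 mg
OBSERVED_N = np.array([[4, 5, 4], [4, 5, 6], [8, 2, 0]])
OBSERVED_Y = np.array([[0, 1, 0], [1, 0, 3], [1, 1, 0]])

BANK_DEPTH = 36  # maximum patients any one combination could ever receive


@dataclass(frozen=True)
class ResponseBank:
    """Fixed ordered binary responses per combination, plus provenance."""

    responses: np.ndarray  # (I, J, BANK_DEPTH) of 0/1
    observed_n: np.ndarray
    observed_y: np.ndarray
    seed: int

    def take(self, comb: Comb, k: int, count: int) -> tuple[int, ...]:
        """Responses k..k+count-1 (0-based) of the combination's list."""
        i, j = comb
        if k + count > BANK_DEPTH:
            raise IndexError("response bank exhausted: more patients than the trial budget")
        return tuple(int(v) for v in self.responses[i - 1, j - 1, k : k + count])


def build_response_bank(
    observed_n: np.ndarray = OBSERVED_N,
    observed_y: np.ndarray = OBSERVED_Y,
    seed: int = 0,
) -> ResponseBank:
    n_obs = np.asarray(observed_n, dtype=int)
    y_obs = np.asarray(observed_y, dtype=int)
    if n_obs.shape != y_obs.shape or np.any(y_obs > n_obs) or np.any(y_obs < 0):
        raise ValueError("invalid observed count matrices")
    rng = np.random.default_rng(seed)
    I, J = n_obs.shape
    bank = np.zeros((I, J, BANK_DEPTH), dtype=np.int8)
    for i in range(I):
        for j in range(J):
            nij, yij = int(n_obs[i, j]), int(y_obs[i, j])
            prefix = np.array([1] * yij + [0] * (nij - yij), dtype=np.int8)
            bank[i, j, :nij] = rng.permutation(prefix)
            n_rest = BANK_DEPTH - nij
            if nij > 0:
                p = rng.beta(1 + yij, 1 + nij - yij, size=n_rest)
            else:
                p = rng.beta(3, 3, size=n_rest)
            bank[i, j, nij:] = (rng.random(n_rest) < p).astype(np.int8)
    return ResponseBank(bank, n_obs, y_obs, int(seed))


def replay(
    design: Design,
    bank: ResponseBank,
    rng: np.random.Generator,
    n_cohorts: int = DEFAULT_N_COHORTS,
    cohort_size: int = DEFAULT_COHORT_SIZE,
) -> TrialResult:
    """Run a design against the fixed response bank.

    The k-th patient a design routes to a combination consumes the k-th
    entry of that combination's response list, so the responses seen depend
    only on the allocation path.  ``rng`` drives only the design's internal
    tie-breaks (and the SFD sampler).
    """
    grid = DoseGrid(*bank.observed_n.shape)
    controller = design.new_trial(grid)
    state = TrialState(grid)
    for _ in range(n_cohorts):
        i, j = state.current
        used = int(state.n[i - 1, j - 1])
        responses = bank.take(state.current, used, cohort_size)
        state.record_cohort(state.current, responses)
        nxt = controller.next_combination(state, rng)
        if nxt is None:
            break
    recommendation = controller.recommend(state, rng)
    return TrialResult(
        recommendation=recommendation,
        allocation=state.n.copy(),
        dlt=state.y.copy(),
        stopped_early=state.stopped,
        decision_log=tuple(state.cohort_log),
    )


def allocation_table(result: TrialResult) -> pd.DataFrame:
    """y/n per cell, the recommended MTC marked with an asterisk."""
    I, J = result.allocation.shape
    rows = []
    for i in range(I):
        row = {}
        for j in range(J):
            cell = f"{result.dlt[i, j]}/{result.allocation[i, j]}"
            if result.recommendation == (i + 1, j + 1):
                cell += "*"
            row[f"B{j + 1}"] = cell
        rows.append(row)
    return pd.DataFrame(rows, index=[f"A{i + 1}" for i in range(I)])
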