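"""Trial simulation loop and operating characteristics.

A simulated trial starts its first cohort at the lowest combination, draws
Bernoulli DLT responses against the scenario's true probabilities, and lets
the design's controller decide each subsequent cohort until the patient
budget (12 cohorts of 3 by default) is spent or the design stops for
safety.  ``run_study`` repeats this over scenarios with independent seeded
substreams and aggregates the standard operating characteristics: PCS
(selections with true toxicity exactly at the target), PAS (selections in
the acceptable band [0.16, 0.33]), overly-toxic selections (> 0.33), mean
patients at overly toxic combinations, the correct-stop proportion, and the
accuracy index A_n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import Design
from .grid import Comb, TrialState
from .scenarios import ToxicityScenario

DEFAULT_N_COHORTS = 12
DEFAULT_COHORT_SIZE = 3

__all__ = [
    "TrialResult",
    "OperatingCharacteristics",
    "run_trial",
    "accuracy_index",
    "run_study",
    "summarise_study",
]


@dataclass(frozen=True)
class TrialResult:
    recommendation: Comb | None
    allocation: np.ndarray  # final patient counts n_ij
    dlt: np.ndarray  # final DLT counts y_ij
    stopped_early: bool
    decision_log: tuple[tuple[Comb, tuple[int, ...]], ...]

    @property
    def n_patients(self) -> int:
        return int(self.allocation.sum())


@dataclass(frozen=True)
class OperatingCharacteristics:
    scenario_id: str
    n_sims: int
    pcs: float
    pas: float
    toxic_selection: float
    patients_toxic: float
    mean_patients: float
    correct_stop: float
    accuracy_index: float | None  # None when the scenario leaves A_n undefined
    selection_props: np.ndarray = field(repr=False)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "pcs": self.pcs,
            "pas": self.pas,
            "toxic_selection": self.toxic_selection,
            "patients_toxic": self.patients_toxic,
            "mean_patients": self.mean_patients,
            "correct_stop": self.correct_stop,
            "accuracy_index": self.accuracy_index,
        }


def run_trial(
    design: Design,
    scenario: ToxicityScenario,
    rng: np.random.Generator,
    n_cohorts: int = DEFAULT_N_COHORTS,
    cohort_size: int = DEFAULT_COHORT_SIZE,
) -> TrialResult:
    """Simulate one trial of the design under the scenario."""
    grid = scenario.grid
    controller = design.new_trial(grid)
    state = TrialState(grid)
    probs = scenario.probs
    for _ in range(n_cohorts):
        i, j = state.current
        responses = tuple((rng.random(cohort_size) < probs[i - 1, j - 1]).astype(int))
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


def accuracy_index(selection_props: np.ndarray, scenario: ToxicityScenario) -> float | None:
    """A_n = 1 - I*J * sum |pi - phi| rho / sum |pi - phi|.

    ``selection_props`` is the matrix of per-combination selection
    proportions (mass on "no recommendation" simply does not appear).  The
    index is 1 when all selection mass sits at true MTCs and 0 for a uniform
    spread; it is undefined (None) when every combination is a true MTC.
    """
    rho = np.asarray(selection_props, dtype=float)
    if rho.shape != scenario.probs.shape:
        raise ValueError("selection proportions must match the scenario grid")
    if rho.sum() > 1 + 1e-9 or np.any(rho < 0):
        raise ValueError("selection proportions must be a sub-probability matrix")
    dev = np.abs(scenario.probs - scenario.target)
    denom = dev.sum()
    if denom <= 0:
        return None
    I, J = scenario.probs.shape
    return float(1.0 - I * J * (dev * rho).sum() / denom)


def _characterise(
    scenario: ToxicityScenario, results: list[TrialResult]
) -> OperatingCharacteristics:
    n_sims = len(results)
    mtc = scenario.mtc_set
    acceptable = scenario.acceptable_set
    toxic = scenario.toxic_set
    toxic_mask = np.zeros(scenario.probs.shape, dtype=bool)
    for (i, j) in toxic:
        toxic_mask[i - 1, j - 1] = True
    sel = np.zeros(scenario.probs.shape)
    pcs = pas = tox = stops = 0
    pts_toxic = 0.0
    pts_total = 0.0
    for r in results:
        pts_toxic += float(r.allocation[toxic_mask].sum())
        pts_total += r.n_patients
        if r.recommendation is None:
            stops += 1
            continue
        sel[r.recommendation[0] - 1, r.recommendation[1] - 1] += 1
        if r.recommendation in mtc:
            pcs += 1
        if r.recommendation in acceptable:
            pas += 1
        if r.recommendation in toxic:
            tox += 1
    sel /= n_sims
    return OperatingCharacteristics(
        scenario_id=scenario.scenario_id,
        n_sims=n_sims,
        pcs=pcs / n_sims,
        pas=pas / n_sims,
        toxic_selection=tox / n_sims,
        patients_toxic=pts_toxic / n_sims,
        mean_patients=pts_total / n_sims,
        correct_stop=stops / n_sims,
        accuracy_index=accuracy_index(sel, scenario),
        selection_props=sel,
    )


def run_study(
    design: Design,
    scenarios: list[ToxicityScenario],
    n_sims: int,
    seed: int | np.random.SeedSequence,
    n_cohorts: int = DEFAULT_N_COHORTS,
    cohort_size: int = DEFAULT_COHORT_SIZE,
) -> dict[str, OperatingCharacteristics]:
    """Independent seeded replicates of each scenario; per-scenario OCs.

    Seeding uses one substream per (scenario, replicate) spawned from the
    root seed, so two studies with equal seeds are identical and the
    patient-level randomness a design faces does not depend on how many
    other scenarios are in the batch.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out: dict[str, OperatingCharacteristics] = {}
    for scen_ss, scenario in zip(root.spawn(len(scenarios)), scenarios):
        streams = scen_ss.spawn(n_sims)
        results = [
            run_trial(design, scenario, np.random.default_rng(ss), n_cohorts, cohort_size)
            for ss in streams
        ]
        out[scenario.scenario_id] = _characterise(scenario, results)
    return out


def summarise_study(
    ocs: dict[str, OperatingCharacteristics],
    mean_over: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy per-scenario table plus an arithmetic-mean row.

    ``mean_over`` restricts which scenarios enter the mean row (the headline
    3x3 comparison averages S1-S13: S14 has no MTC and is summarised by its
    correct-stop rate, S15 leaves PCS/A_n degenerate).
    """
    rows = []
    for sid, oc in ocs.items():
        rows.append({"scenario": sid, "n_sims": oc.n_sims, **oc.as_dict()})
    df = pd.DataFrame(rows).set_index("scenario")
    ids = mean_over if mean_over is not None else list(ocs.keys())
    mean_cols = ["pcs", "pas", "toxic_selection", "patients_toxic", "mean_patients"]
    mean_row = df.loc[[s for s in ids if s in df.index], mean_cols].mean()
    df.loc["mean"] = mean_row
    return df
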