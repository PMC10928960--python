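"""Common contract implemented by every dose-escalation design.

A design is an immutable configuration object; ``new_trial`` returns a
per-trial controller.  The simulation engine drives the controller: after
each cohort's responses are recorded in the :class:`~combocal.grid.TrialState`
it calls :meth:`TrialController.next_combination`, which applies the design's
overdose rule (possibly setting ``state.stopped``) and returns the next
combination, or ``None`` when the trial terminates for safety.  At the end
of the trial :meth:`TrialController.recommend` yields the single recommended
MTC, or ``None``.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from .grid import Comb, DoseGrid, TrialState

__all__ = ["Design", "TrialController", "choose_max", "choose_min_distance"]


class TrialController(ABC):
    """Per-trial decision logic; may carry mutable design-internal state."""

    @abstractmethod
    def next_combination(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        """Return the combination for the next cohort, or None on a safety stop."""

    @abstractmethod
    def recommend(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        """Final single-MTC recommendation (None if stopped for safety)."""


class Design(ABC):
    """Immutable design configuration."""

    name: str = "design"

    @abstractmethod
    def new_trial(self, grid: DoseGrid) -> TrialController:
        ...


def choose_max(
    candidates: list[Comb],
    score: dict[Comb, float],
    rng: np.random.Generator,
    tol: float = 1e-12,
) -> Comb:
    """Candidate with maximal score; exact ties resolved uniformly at random."""
    best = max(score[c] for c in candidates)
    ties = [c for c in candidates if score[c] >= best - tol]
    if len(ties) == 1:
        return ties[0]
    return ties[int(rng.integers(len(ties)))]


def choose_min_distance(
    candidates: list[Comb],
    estimate: dict[Comb, float],
    target: float,
    rng: np.random.Generator,
    tol: float = 1e-12,
) -> Comb:
    """Candidate whose estimate is closest to the target; ties random."""
    return choose_max(candidates, {c: -abs(estimate[c] - target) for c in candidates}, rng, tol)
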