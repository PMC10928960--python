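"""Toxicity scenarios: true DLT-probability surfaces with a target rate.

The 21 study scenarios (3x3 grids S1-S15, 2x3 grids S16-S18, 2x4 grids
S19-S21) ship as a YAML package fixture and are loaded by id.  A combination
with true toxicity exactly equal to the target (0.30) is a true MTC; one
with toxicity in [0.16, 0.33] is "acceptable"; anything above 0.33 is
"overly toxic".
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .grid import Comb, DoseGrid

ACCEPTABLE_BAND = (0.16, 0.33)
OVERLY_TOXIC_ABOVE = 0.33
_MTC_TOL = 1e-9

__all__ = ["ToxicityScenario", "load_scenario", "load_scenarios", "scenario_ids", "ACCEPTABLE_BAND", "OVERLY_TOXIC_ABOVE"]


@dataclass(frozen=True)
class ToxicityScenario:
    """True DLT probabilities on a dose grid plus the target toxicity."""

    scenario_id: str
    probs: np.ndarray
    target: float = 0.30

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2:
            raise ValueError("probs must be a 2-D matrix")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("toxicity probabilities must lie in (0, 1)")
        if not 0 < self.target < 1:
            raise ValueError("target must lie in (0, 1)")

    @property
    def grid(self) -> DoseGrid:
        return DoseGrid(*self.probs.shape)

    def prob(self, comb: Comb) -> float:
        return float(self.probs[comb[0] - 1, comb[1] - 1])

    def _cells(self, mask: np.ndarray) -> frozenset[Comb]:
        return frozenset((int(i) + 1, int(j) + 1) for i, j in zip(*np.nonzero(mask)))

    @property
    def mtc_set(self) -> frozenset[Comb]:
        """Combinations whose true toxicity equals the target exactly."""
        return self._cells(np.abs(self.probs - self.target) < _MTC_TOL)

    @property
    def acceptable_set(self) -> frozenset[Comb]:
        lo, hi = ACCEPTABLE_BAND
        return self._cells((self.probs >= lo - _MTC_TOL) & (self.probs <= hi + _MTC_TOL))

    @property
    def toxic_set(self) -> frozenset[Comb]:
        return self._cells(self.probs > OVERLY_TOXIC_ABOVE + _MTC_TOL)


@lru_cache(maxsize=1)
def _registry() -> dict:
    text = resources.files("combocal.data").joinpath("scenarios.yaml").read_text()
    return yaml.safe_load(text)


def scenario_ids() -> list[str]:
    return list(_registry()["scenarios"].keys())


def load_scenario(scenario_id: str) -> ToxicityScenario:
    reg = _registry()
    try:
        probs = reg["scenarios"][scenario_id]
    except KeyError:
        raise KeyError(f"unknown scenario id {scenario_id!r}; known: S1..S21") from None
    return ToxicityScenario(scenario_id, np.array(probs, dtype=float), float(reg["target"]))


def load_scenarios(ids: list[str] | None = None) -> list[ToxicityScenario]:
    if ids is None:
        ids = scenario_ids()
    return [load_scenario(s) for s in ids]
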