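"""Model-free dual-agent phase I dose-escalation designs.

Five model-free designs for dual-agent combination dose finding -- BOIN,
Keyboard, Surface-Free, PIPE and Waterfall -- together with a two-stage
calibration procedure (geometric-mean-PCS hyper-parameter search, then
overdose-threshold selection against an all-toxic scenario), a simulation
engine for operating characteristics, and a deterministic case-study
replay harness.
"""

__version__ = "0.1.0"

from .grid import BetaParams, DoseGrid, TrialState, admissible_moves, matrix_isotonic
from .interval import BoinConfig, KeyConfig, boin_thresholds, key_partition
from .pipe import PipeDesign, pipe_build_prior
from .scenarios import ToxicityScenario, load_scenario, load_scenarios
from .sfd import SfdDesign, sfd_build_prior
from .simulate import run_study, run_trial, summarise_study
from .waterfall import WaterfallDesign, partition_subtrials

__all__ = [
    "__version__",
    "BetaParams",
    "DoseGrid",
    "TrialState",
    "ToxicityScenario",
    "BoinConfig",
    "KeyConfig",
    "PipeDesign",
    "SfdDesign",
    "WaterfallDesign",
    "admissible_moves",
    "matrix_isotonic",
    "boin_thresholds",
    "key_partition",
    "pipe_build_prior",
    "sfd_build_prior",
    "partition_subtrials",
    "load_scenario",
    "load_scenarios",
    "run_trial",
    "run_study",
    "summarise_study",
]


def default_designs(target: float = 0.30) -> dict[str, object]:
    """The five designs at their calibrated configurations."""
    return {
        "boin": BoinConfig(target=target),
        "keyboard": KeyConfig(target=target),
        "sfd": SfdDesign(target=target),
        "pipe": PipeDesign(target=target),
        "waterfall": WaterfallDesign(target=target),
    }
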