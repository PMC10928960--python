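"""Surface-free design (SFD).

Rather than modelling each combination independently or through a parametric
dose-toxicity surface, the SFD parametrises *ratios* of no-DLT
probabilities: theta = 1 - pi_11, row ratios theta_i = (1-pi_ij)/(1-pi_{i-1,j})
and column ratios tau_j = (1-pi_ij)/(1-pi_{i,j-1}).  Monotonicity puts every
ratio in (0,1), each gets an independent Beta prior, and the toxicity
surface pi_ij = 1 - theta * theta_2..theta_i * tau_2..tau_j is monotone in
both drugs within every posterior draw.  Escalation picks, among the
extended admissible neighbours, the combination whose posterior-mean
toxicity is closest to the target; a per-cell overdose rule bars any
combination with P(pi_ij > phi | data) >= epsilon and stops the trial when
the lowest combination is barred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mcmc import sfd_mcmc, surface_from_ratios
from .designs import Design, TrialController, choose_min_distance
from .grid import BetaParams, Comb, DoseGrid, TrialState, admissible_moves

__all__ = ["SfdPrior", "McmcSettings", "sfd_build_prior", "ratios_to_prob", "SfdPosterior", "sfd_posterior_sample", "SfdDesign"]


@dataclass(frozen=True)
class SfdPrior:
    """Independent Beta priors for (theta, theta_2..theta_I, tau_2..tau_J)."""

    grid: DoseGrid
    ratio_priors: tuple[BetaParams, ...]

    def __post_init__(self) -> None:
        k_expected = 1 + (self.grid.n_rows - 1) + (self.grid.n_cols - 1)
        if len(self.ratio_priors) != k_expected:
            raise ValueError(f"expected {k_expected} ratio priors, got {len(self.ratio_priors)}")

    @property
    def a(self) -> np.ndarray:
        return np.array([p.alpha for p in self.ratio_priors])

    @property
    def b(self) -> np.ndarray:
        return np.array([p.beta for p in self.ratio_priors])

    def prior_mean_surface(self) -> np.ndarray:
        """Plug-in surface from the prior mean ratios (exact for the mean of
        pi because the ratios are independent)."""
        means = np.array([p.mean for p in self.ratio_priors])
        I, J = self.grid.shape
        row = np.concatenate([[1.0], np.cumprod(means[1:I])])
        col = np.concatenate([[1.0], np.cumprod(means[I : I + J - 1])])
        return 1.0 - means[0] * np.outer(row, col)


def sfd_build_prior(m: float, s: float, grid: DoseGrid) -> SfdPrior:
    """Equal-mean-ratio prior: every ratio ~ Beta(m*s, (1-m)*s).

    The implied prior mean toxicity at (i, j) is 1 - m^(i+j-1), rising along
    anti-diagonals; s is the effective sample size of each ratio prior.
    """
    if not 0 < m < 1 or s <= 0:
        raise ValueError("need 0 < m < 1 and s > 0")
    k = 1 + (grid.n_rows - 1) + (grid.n_cols - 1)
    return SfdPrior(grid, tuple(BetaParams(m * s, (1 - m) * s) for _ in range(k)))


def ratios_to_prob(theta: float, row_ratios, col_ratios, i: int, j: int) -> float:
    """pi_ij = 1 - theta * prod(theta_2..theta_i) * prod(tau_2..tau_j)."""
    surv = theta
    for k in range(i - 1):
        surv *= row_ratios[k]
    for k in range(j - 1):
        surv *= col_ratios[k]
    return 1.0 - surv


@dataclass(frozen=True)
class McmcSettings:
    iterations: int = 20_000
    burn_in: int = 5_000

    def __post_init__(self) -> None:
        if not 0 < self.burn_in < self.iterations:
            raise ValueError("need 0 < burn_in < iterations")


@dataclass(frozen=True)
class SfdPosterior:
    """Joint posterior draws of the ratios and the derived toxicity surface."""

    ratio_draws: np.ndarray  # (n_draws, K), probability scale
    surfaces: np.ndarray  # (n_draws, I, J)
    accept_rate: float

    @property
    def mean_surface(self) -> np.ndarray:
        return self.surfaces.mean(axis=0)

    def tail_prob(self, threshold: float) -> np.ndarray:
        """P(pi_ij > threshold | data) per cell, from the draws."""
        return (self.surfaces > threshold).mean(axis=0)


def sfd_posterior_sample(
    prior: SfdPrior,
    state: TrialState,
    mcmc: McmcSettings,
    seed: int,
) -> SfdPosterior:
    """Sample the ratio posterior by random-walk Metropolis (numba kernel)."""
    I, J = prior.grid.shape
    draws, acc = sfd_mcmc(
        state.y.astype(np.float64),
        state.n.astype(np.float64),
        prior.a.astype(np.float64),
        prior.b.astype(np.float64),
        I,
        J,
        mcmc.iterations,
        mcmc.burn_in,
        seed,
    )
    return SfdPosterior(draws, surface_from_ratios(draws, I, J), acc)


@dataclass(frozen=True)
class SfdDesign(Design):
    """Calibrated surface-free configuration."""

    target: float = 0.30
    m: float = 0.875
    s: float = 4.0
    epsilon: float = 0.65
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    name = "sfd"

    def new_trial(self, grid: DoseGrid) -> "_SfdController":
        return _SfdController(self, grid)


class _SfdController(TrialController):
    def __init__(self, cfg: SfdDesign, grid: DoseGrid) -> None:
        self.cfg = cfg
        self.grid = grid
        self.prior = sfd_build_prior(cfg.m, cfg.s, grid)
        self._posterior: SfdPosterior | None = None

    def _refresh(self, state: TrialState, rng: np.random.Generator) -> SfdPosterior:
        seed = int(rng.integers(2**31 - 1))
        self._posterior = sfd_posterior_sample(self.prior, state, self.cfg.mcmc, seed)
        return self._posterior

    def next_combination(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        post = self._refresh(state, rng)
        means = post.mean_surface
        if self.cfg.epsilon < 1.0:
            # cell-wise rule, re-evaluated from the current posterior each
            # cohort; the monotone surface makes orthant propagation implicit
            tails = post.tail_prob(self.cfg.target)
            flagged = {(i + 1, j + 1) for i, j in zip(*np.nonzero(tails >= self.cfg.epsilon))}
            state.eliminated = flagged
            if (1, 1) in flagged:
                state.stopped = True
                return None
        admissible = admissible_moves(state.current, "extended", self.grid, state.eliminated)
        if not admissible:
            nxt = state.current  # current safe but boxed in: stay
        else:
            est = {c: float(means[c[0] - 1, c[1] - 1]) for c in admissible}
            nxt = choose_min_distance(sorted(admissible), est, self.cfg.target, rng)
        state.current = nxt
        return nxt

    def recommend(self, state: TrialState, rng: np.random.Generator) -> Comb | None:
        if state.stopped:
            return None
        post = self._refresh(state, rng)
        means = post.mean_surface
        tested = [c for c in state.tested() if c not in state.eliminated]
        if not tested:
            return None
        est = {c: float(means[c[0] - 1, c[1] - 1]) for c in tested}
        return choose_min_distance(tested, est, self.cfg.target, rng)
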