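# Methods

`combocal` implements five *model-free* designs for dual-agent phase I
dose-escalation trials, a two-stage calibration procedure for their
hyper-parameters, a simulation engine for operating characteristics, and a
deterministic case-study replay harness.  This note records the models, the
numerical choices, and the places where the designs' published descriptions
left genuine freedom.

## Setting and notation

A trial explores an I x J grid of combinations d_ij of two drugs with
ordered dose levels (i indexes drug A, j drug B).  Patients enter in
cohorts (three by default, twelve cohorts in total) and each contributes a
binary dose-limiting-toxicity (DLT) outcome; y_ij of the n_ij patients
treated at d_ij had DLTs.  Toxicity is assumed monotone in each drug.  The
goal is the maximum tolerated combination (MTC): the combination whose true
DLT probability pi_ij is closest to the target phi = 0.30.  A combination
with pi in [0.16, 0.33] is *acceptable*; one with pi > 0.33 is *overly
toxic*.  All designs start at (1,1), never escalate both drugs at once, and
never skip levels; the surface-free and PIPE designs additionally allow
diagonal de-escalation and anti-diagonal moves.

## The designs

**BOIN.**  Escalation compares the raw rate y/n at the current combination
with boundaries (lambda_e, lambda_d), closed-form functions of phi and the
band (phi1, phi2) = (a1 phi, a2 phi); the calibrated a1 = 0.65, a2 = 1.4
give (0.245, 0.359).  Within the chosen escalation/de-escalation set
{(i+1,j),(i,j+1)} / {(i-1,j),(i,j-1)} the combination maximising
P(pi in (lambda_e, lambda_d)) under independent Beta(1,1) posteriors is
chosen (untested members keep the vague prior and tie uniformly at random).
A combination with P(pi > phi | y, n) >= epsilon (0.84 calibrated) is
eliminated with its whole upper orthant; eliminating (1,1) stops the trial.
The final MTC is the tested, non-eliminated combination whose matrix
isotonic estimate is closest to phi.

**Keyboard.**  Identical machinery, but the decision statistic is the
posterior-modal "key": (0,1) is tiled by intervals the width of the target
key (b1, b2) = (0.21, 0.39), shorter at the edges, and the design
escalates/stays/de-escalates according to whether the key with the largest
posterior mass is below/at/above the target key.  An exact tie between keys
(possible only for flat posteriors) resolves toward the target key, i.e.
toward staying.

**Surface-free (SFD).**  Parametrises ratios of no-DLT probabilities:
theta = 1 - pi_11, row ratios theta_i, column ratios tau_j, each in (0,1)
with independent Beta priors; pi_ij = 1 - theta prod theta_2..i prod
tau_2..j is monotone by construction in every posterior draw.  The
calibrated prior takes every ratio ~ Beta(3.5, 0.5) (mean ratio m = 0.875,
effective sample size s = 4), implying prior mean toxicities 0.125 at (1,1)
and 0.487 at (3,3).  After each cohort the posterior is sampled by MCMC;
the design moves to the admissible (extended-family) combination whose
posterior-mean toxicity is closest to phi, among cells not flagged by the
cell-wise rule P(pi_ij > phi | data) >= epsilon (0.65 calibrated; the
flagged set is recomputed from each new posterior rather than accumulated,
since the monotone surface already propagates evidence).  The trial stops
when (1,1) is flagged.  The design's published description ends at "the MTC
is the combination with toxicity closest to phi"; we select among *tested*,
unflagged combinations by posterior mean, consistent with the package-wide
convention that a never-administered combination is not recommendable.

**PIPE.**  Independent Beta(a_ij, b_ij) priors per cell; the object of
inference is the MTC *contour*, a monotone 0/1 matrix separating cells
believed below/above phi.  All C(I+J, I) monotone contours are enumerated;
a contour's posterior score is prod p_ij^(1-C) (1-p_ij)^C with
p_ij = P(pi_ij <= phi | data), normalised across contours.  Dosing picks,
among admissible non-barred cells below the modal contour, those nearest
the boundary (lattice distance), randomised with weights 1/(n_ij + 1); the
overdose rule bars any *tested* cell whose posterior expected above-contour
indicator q_ij = sum_C C[i,j] P(C | data) reaches epsilon (0.50
calibrated), re-evaluated every cohort, and stops the trial when (1,1) is
barred.  At the end, the tested cells closest below the final modal
contour are the recommendation set; cells with posterior mean <= phi are
preferred (they are the ones genuinely believed below the contour) and the
posterior mean closest to phi wins.

Priors are elicited per anti-diagonal segment: level rho + (i+j-2) delta
with rho = 0.05, delta = 0.025, and per-cell prior sample size s = 1/18.
The hyper-parameters match the prior **median** to the elicited level
(a + b = s solved so the Beta median equals it), following the reference
PIPE convention.  This matters enormously at these tiny sample sizes: a
Beta with a + b = 1/18 is a two-point-like distribution, so mean-matching
at level 0.05 would put ~94% of prior mass below any plausible target and
untested cells would dominate the contour posterior, whereas
median-matching leaves them essentially non-informative.  Mean-matching is
available via `pipe_build_prior(..., parametrisation="mean")`.  Similarly,
the overdose rule is restricted to tested cells because q_ij is driven by
contour *multiplicity* as much as by data: the top corner has q ~ 0.93
before any patient is treated, and a prior-triggered permanent elimination
would make the upper grid unreachable in every trial.

**Waterfall.**  Decomposes the grid into I sub-trials run sequentially with
the single-agent BOIN rule and the same (lambda_e, lambda_d) and epsilon =
0.84: S_I climbs the first column and then row I; each S_k (k < I) covers
row k from column 2.  Cohort budgets are fixed per sub-trial (6/3/3 on 3x3,
8/4 on 2xJ; generically the first sub-trial gets twice each later one's
share).  When a sub-trial's budget is spent, its "candidate MTD" is the
1-D isotonic estimate closest to phi among its tested, non-eliminated
doses; a candidate in row i* hands off to S_{i*-1}, starting at column
j*+1 clipped into the sub-trial's range (the hand-off start is not printed
in the design's description; this follows the original proposal's logic).
If every dose of a sub-trial is eliminated its remaining cohorts are
forfeited and the candidate defaults to (k, 1); eliminating (1,1) stops
the whole trial.  The final step selects, per row, the tested dose with
matrix-isotonic estimate closest to phi (rows whose tested doses are all
eliminated are skipped), and reduces this contour to one MTC by the
Beta(1,1) posterior mean.

## Shared numerics

*Matrix isotonic regression* is the weighted least-squares projection onto
the bimonotone cone, computed by Dykstra's alternating projections with
exact weighted pool-adjacent-violators passes over rows and columns
(tolerance 1e-10, cap 10,000 sweeps).  The Dykstra correction terms matter:
plain cyclic row/column PAVA converges to a feasible matrix but not to the
projection, and the test suite pins the projection against a brute-force
constrained optimiser on random 2x2 and 2x3 instances.  Untested cells
(weight 0) receive a pseudo-weight of 1e-8 times the smallest positive
weight: they are filled by monotone extension without influencing the
tested cells.  Ties in closest-to-phi selections prefer the combination
with more patients, then a uniform draw from the trial's seeded generator.

*Interval-design decision tables.*  All Beta posterior interval and tail
probabilities that BOIN/Keyboard/Waterfall need are exact regularised
incomplete-beta values, precomputed once per configuration as (n, y) lookup
tables up to n = 36.

*SFD sampler.*  Component-wise random-walk Metropolis on logit-transformed
ratios, numba-compiled, 20,000 iterations with 5,000 burn-in by default and
per-coordinate step adaptation toward ~35% acceptance during burn-in.  The
sampler is validated against the conjugate posterior on a 1x1 grid and
3-dimensional tensor-product Gauss-Legendre quadrature on a 2x2 grid
(agreement within 0.01).  Whole-study SFD simulations use a reduced
4,000/1,000 sampler and 200-300 replicates per scenario; the reduced
sampler reproduces the full sampler's operating characteristics within
Monte-Carlo noise at a fraction of the cost.

*Epsilon = 1* disables every overdose rule exactly (the rules use ">=" and
a posterior tail probability cannot reach 1 with finite data), which is how
stage-1 calibration runs without stopping.

## Calibration

Stage 1 grid-searches hyper-parameters with overdose rules disabled over
four contrasting scenarios (S1, S8, S10, S13), scoring each cell by the
*geometric* mean PCS -- for a fixed arithmetic mean, dispersion across
scenarios strictly lowers the score.  Grids: BOIN a1 in {0.40..0.85} x a2
in {1.15..1.60} (100 cells), Keyboard b1 in {0.19..0.27} x b2 in
{0.33..0.41} (25), SFD m in {0.85..0.95} x s in {1..5} (25), PIPE rho,
delta in {0.025..0.10} x s in {1/72..1/9} (64); Waterfall reuses BOIN's
interval.  Grid cells are evaluated with common random numbers (every cell
sees the same patient-level substreams), the standard variance-reduction
device for simulation-based comparisons: differences across the surface are
then design effects rather than sampling noise.  The surface itself is a
broad plateau -- on the BOIN grid essentially every a2 >= 1.25 performs
within about one percentage point of geometric-mean PCS regardless of a1 --
so the meaningful calibration output is membership in that plateau, not a
unique argmax.  Stage 2 lowers epsilon from 1 on a 0.01 grid until at least 85%
of trials in the all-toxic scenario S14 recommend no combination, tracking
safety and PCS curves over S8, S10, S13, S14.  Reference replicate counts
are 4000 (BOIN/KEY), 2000 (PIPE) and 1000 (SFD) per cell; tests run reduced
counts and check the known winner lands in the top decile, which is robust
to Monte-Carlo noise.

## Simulation engine and metrics

`run_trial` draws cohort responses as Bernoulli(pi) against the scenario's
true matrix and delegates decisions to the design controller;
no accuracy-based or sufficient-information stopping is applied, so only
safety can end a trial early.  `run_study` spawns one RNG substream per
(scenario, replicate) from the root seed: results are bitwise reproducible
and independent of batch composition.  Per scenario we report PCS
(selection with true pi exactly 0.30, compared at 1e-9), PAS (true pi in
[0.16, 0.33]), overly-toxic selections (pi > 0.33), mean patients at overly
toxic combinations, mean patients overall, the correct-stop proportion, and
the accuracy index A_n = 1 - IJ sum |pi - phi| rho / sum |pi - phi| (rho
the selection proportions; undefined for a flat scenario at the target, as
in the all-safe S15, which is reported descriptively and excluded from
cross-scenario means along with the no-MTC S14).

Replicate counts: the bundled acceptance script uses 2000 per scenario for
BOIN/Keyboard/PIPE and 500 for the SFD safety scenario; the test suite's
study-level checks use 2000 (fast designs) and 300 at the reduced sampler
(SFD).  Monte-Carlo tolerances are three standard errors of the quantity
at its replicate count.

## The case-study replay

The replay converts the observed counts of a real neratinib + temsirolimus
combination trial (restricted to a 3x3 grid) into a fixed bank of 36
ordered responses per combination: a seed-fixed permutation of the observed
y_ij ones and n_ij - y_ij zeros, then simulated patients whose individual
DLT probability is drawn once from Beta(1 + y_ij, 1 + n_ij - y_ij) --
or Beta(3, 3) where the combination was never dosed, encoding that
non-escalation usually signals concern.  Every design consumes the same
bank, so two designs that walk the same allocation path see identical
responses; differences in the final tables isolate escalation behaviour.
Post-prefix responses are random beyond the observed data, so panel-level
agreement with any particular published replay is qualitative, not exact.

## What the synthetic data does and does not emulate

Scenario-based Bernoulli simulation captures the decision-theoretic content
of the designs -- allocation, stopping, selection -- under known truth, which
is the standard evidence for design operating characteristics.  It does not
model accrual over time, within-cohort heterogeneity, attributable-vs-
unrelated toxicity adjudication, or partial follow-up; passing tests say
nothing about those aspects of real trials.  The printed scenario matrices
are exact package fixtures (checksum-pinned), not samples.

## Known limitations

- The Keyboard design reproduces its published decision rules but lands
  ~4-5 percentage points below the reference study's mean PCS; BOIN, whose
  machinery it shares, matches its reference per-scenario accuracy indices
  closely.  We did not find a reading of the key rule that closes the gap
  without breaking the printed key partition.
- PIPE's cross-scenario mean PCS settles near 26-27% against a reference
  31.2%, while its four safety/selection signatures (all-toxic stopping,
  patients before stopping, S1 PCS, mean overly-toxic selections)
  reproduce; the residual gap likely sits in unpublished recommendation
  details.
- Contour enumeration is exact and therefore limited to grids of at most
  20 cells (C(I+J, I) contours); larger grids need a different PIPE
  posterior representation.
- The SFD sampler is tuned for the <= 7-parameter surfaces of the study's
  grids; much larger grids would warrant a gradient-based sampler.
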