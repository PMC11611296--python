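# Methods

## The system and the observable

A transcriptional riboswitch senses its ligand by shifting the balance among a
small number of RNA conformations. For the guanidinium-responsive aptamer this
package targets, single-molecule FRET resolves three states — an unfolded, a
pre-folded (compacted) and a folded conformation in which a long-range
kissing-loop closes — with proximity ratios near E ≈ 0.2, 0.5 and 0.8. The
per-frame observable is the uncorrected proximity ratio

    E[t] = I_A[t] / (I_A[t] + I_D[t])

from the donor and acceptor intensities on a 0.1 s frame clock. No gamma
factor, spectral crosstalk or background model is applied beyond an optional
constant offset per channel; the analysis operates on the same quantity the
raw two-channel recording defines. Frames at or after the earliest
photobleach, frames with nonpositive total intensity, and frames whose ratio
falls outside [0, 1] (a physical impossibility, produced only by noise
driving one channel far negative) are masked invalid and never imputed.
Masking the out-of-range frames matters more than it looks: a single 12-sigma
ratio outlier is worth tens of log-likelihood units to a spurious extra HMM
component, and a handful of them can flip BIC model selection.

## Trajectory model and simulator

Conformational dynamics are a continuous-time Markov chain: a K×K rate matrix
Q with nonnegative off-diagonal rates (s⁻¹) and rows summing to zero. The
exit rate of state i is −Q[i,i] = 1/τ_i. Trajectories are simulated exactly
(Gillespie): exponential holding times, next state proportional to the
off-diagonal rates. The default three-state model is a linear chain
unfolded ↔ pre-folded ↔ folded with lifetimes τ = (0.69, 0.11, 0.40) s, the
aptamer's values at 2 mM Mg²⁺; the pre-folded state's exits split evenly
between its neighbours. A variant with lifetimes (0.60, 0.11, 1.04) s stands
in for the ligand-bound condition, in which occupancy switches to favour the
folded state.

The camera sees the state at each frame's midpoint (point sampling). Frames
are not time-averaged over the exposure; transitions faster than the 0.1 s
frame are therefore blurred exactly as in the recordings this emulates, and a
time-averaging emitter is a documented extension, not a default.

Emission: in state s each frame draws a FRET value from
Normal(E_s, efret_sd) truncated to [0, 1]; the channels are then
acceptor = I₀·E + ε_A, donor = I₀·(1−E) + ε_D with independent
Normal(0, σ) noise per channel. Defaults: I₀ = 1000 (a.u.), σ = 50,
efret_sd = 0.05, 600 frames per trace — separations of ≈ 4.5 combined SDs
between neighbouring states, enough that idealization is reliable but not
trivial. There is no Poisson shot noise, crosstalk or gamma factor, matching
the uncorrected observable analysed downstream. Photobleaching is single-step
and per-dye with exponential times; after acceptor bleach the excitation
reroutes to the donor (donor rises to I₀), after donor bleach both channels
drop to background. Post-bleach frames are kept but flagged so QC and the
E-computation can truncate, as with real traces.

What the generator does not emulate: camera/EMCCD noise physics, diffuse
background, blinking and other reversible photophysics, molecule-to-molecule
static heterogeneity of the FRET means, and baseline drift. Passing recovery
tests on these synthetics therefore demonstrates correctness of the
estimators under the stated noise model, not robustness to every artifact of
real recordings.

Ligand coupling: a titration law (Hill curve with midpoint, slope n, floor
and ceiling) sets the folded state's stationary occupancy at each
concentration. The rate matrix is retuned per concentration by rescaling the
folded state's exit (unfolding) rates with a factor found by 1-D
root-finding; occupancy of the folded state is monotone in that factor, so
any target in (0, 1) is reachable exactly, and the lifetimes of the other
states are untouched. This realises ligand action as stabilisation of the
folded state (populations shift, state FRET values do not). Rescaling the
folding (inbound) rates instead would alter the non-folded lifetimes, which
the generator deliberately preserves as its invariant.

## Idealization: Gaussian-emission HMM

One model per experimental condition is fitted jointly to all traces (shared
means, SDs, transition matrix and initial distribution), matching how
per-condition histograms and kinetics are reported; per-trace fits are
available by calling the fitter on single traces. Estimation is
maximum-likelihood Baum–Welch EM with scaled (normalised) forward–backward
recursions; the log-likelihood is non-decreasing across iterations and this
is asserted in tests. Convergence: ΔlogL < 1e-6 or 500 iterations, the
non-converged case returned with a warning flag. Emission SDs are floored at
1e-3 so noiseless data cannot collapse a component's variance. Masked frames
split a trace into independent observation sequences; the chain is never
bridged across a gap.

Initialization and restarts: the first start uses quantile-spaced means over
the pooled E values with a shared SD of pooled-SD/√K and transition
self-probability 0.95; the second start spreads means evenly over the pooled
range (quantile placement alone collapses into the dominant peak when one
state holds ~90% of the frames, as in high-Mg²⁺ ensembles); further restarts
jitter the quantile means with seeded noise. The best restart by
log-likelihood is kept. Everything is deterministic given the seed. States
are always reported in canonical order of ascending mean E, which makes
relabelled fits comparable.

Model selection scores each candidate K with BIC = −2 logL + p ln(n), where
p = (K² − K) + (K − 1) + 2K free parameters and n is the number of valid
frames, and returns the arg-min. Decoding is Viterbi in log space with ties
broken toward the lower state index. Both recursions are verified against
exhaustive enumeration over all K^T paths on small instances, and the E-step
has a compiled (numba) implementation, numerically equivalent to the pure
numpy reference path that remains in the module.

This is a deliberate substitution for the variational-Bayes estimator
commonly used in this field: ML-EM with BIC is deterministic, fully
specified, and testable against enumeration oracles; a VB backend is an
extension point, not a default.

## Dwell times and kinetics

A dwell is a maximal run of consecutive frames in one state; its duration is
frames × 0.1 s. The first and last dwell of each contiguous valid run are
flagged censored (their start or end is unobserved) and excluded from the
default fit. The default lifetime estimator is the exponential MLE — the mean
of the uncensored dwells — with the exact chi-square interval for the
exponential mean (2S/τ ~ χ²(2n)); a censoring policy that keeps
right-censored dwells in the standard censored-exponential likelihood, and a
binned least-squares fit of the dwell histogram to A·exp(−t/τ) mirroring the
classic plot-and-fit procedure, are both provided. The MLE is the default
because it is binning-free and its interval is exact.

Discretization bias is real and documented rather than corrected: with
lifetimes near the frame interval (τ = 0.11 s ≈ 1.1 frames), about a third of
the middle state's visits fall between frame midpoints and vanish, merging
the neighbouring dwells. At the default aptamer kinetics this inflates
frame-derived lifetimes by roughly +27%/+64%/+34% for the three states, while
the same estimator on the generator's continuous-time dwells recovers all
three within ~1%. Missed-event (blur) corrections are out of scope; the
package asserts the qualitative property τ̂ ≥ τ for frame-derived dwells and
quantitative recovery for the estimator itself.

Transition density plots count one point per state change at (mean E of the
departing segment, mean E of the arriving segment), using raw segment-mean E
rather than fitted state means so that misassignment smear stays visible.
Note that with a fast intermediate state, apparent direct low↔high
transitions in a TDP are expected from single-frame pass-throughs even when
no direct rate exists.

## Populations and free energies

State populations default to occupancy: the fraction of valid frames
Viterbi-assigned to each state, with an SD from bootstrapping whole molecules
(molecules, not frames, are the exchangeable unit). A Gaussian-mixture fit of
the pooled E values is reported alongside as the histogram-based estimate;
occupancy is the default because it shares its model with the kinetics,
keeping P and τ internally consistent.

Relative free energy between states uses

    ΔΔG_ab = −R·T·ln(P_b / P_a)

with state a the control, R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ (kJ switchable) and
T = 293.15 K by default (measurements at 20 °C). It is computed as
RT·(ln P_a − ln P_b) so antisymmetry is exact in floating point; additivity
along a path holds to rounding. Uncertainty propagates from the population
SDs by the delta method, neglecting the (anti-)covariance between the two
fractions, which makes the reported SD mildly conservative for complementary
states. Zero populations are rejected with guidance (pseudocount or bound)
rather than silently regularised.

Two normalisation rules for folded-fraction series are implemented — divide
by the series maximum, or paired difference relative to a reference entry —
and every output records which rule produced it; no claim is made about which
rule the field's figures use, since that is generally unstated.

## Dose–response

Titrations are fitted by nonlinear least squares on a log-concentration axis:
Hill (floor, ceiling, EC50, n) and one-site (n ≡ 1, midpoint reported as K_d,
chosen for binding isotherms because a dissociation constant, not an apparent
EC50, is the quantity of interest; the free-n fit is available as a
sensitivity check). Replicates enter the loss individually. The optimiser is
multi-started from 7 log-spaced midpoint seeds spanning the tested range with
the midpoint bounded in [min_c/10, 10·max_c], the amplitude parametrised as
ceiling − floor ≥ 0 so floor < ceiling by construction, and standard errors
taken from the Jacobian at the optimum (midpoint SE by the delta method from
log-midpoint). Fits that do not converge or whose midpoint leaves the tested
range are returned with a warning, not discarded.

The co-transcriptional window summary tabulates folded fractions of halted
elongation complexes with and without ligand across nascent-RNA lengths,
their absolute increase and the normalised increase under a declared rule,
and reports the arg-max length — the computational analogue of locating the
ligand-sensitive transcription window.

## Problem sizes and determinism

Every stochastic routine takes a seed and is byte-reproducible given it.
The scripted acceptance run uses: 200 random small instances for the
enumeration oracles; 20 independent ensembles of 200 traces × 600 frames for
state-count selection (restart count 2 there, balancing restart coverage
against the cost of 100 EM fits); 150 traces × 600 frames for lifetime
recovery; 60 traces × 300 frames per condition for the free-energy sign
check; 100 replicate tables for EC50 recovery statistics; 30 traces × 250
frames per EC-length condition for the window summary; and, for the titration
midpoints, the median fit over 10 independent read-through assays (10
concentrations, n = 3) and over 5 independent folded-fraction titrations
(8 concentrations, 100 traces × 400 frames each) — a single synthetic
experiment's midpoint scatters about as much as such experiments do, so a
median over replicate experiments is what gets reported. The test suite runs
the same
checks at equal per-ensemble conditions but fewer repetitions where a
repetition count, not a condition, is what shrinks.

## Known limitations

- No correction for gamma, crosstalk, background or blur; estimates describe
  the proximity-ratio process, not photophysically corrected distances.
- Frame-derived lifetimes are biased upward when any state's lifetime
  approaches the frame interval (see above); compare like with like.
- BIC selection counts every valid frame as independent evidence; with very
  long recordings it will punish even small emission-model misfit, so the
  validity mask (especially the [0, 1] ratio rule) is load-bearing.
- The Hill/one-site fits assume additive homoscedastic replicate noise on the
  response fraction; heteroscedastic weighting is not implemented.
- Titration simulation couples ligand only to the folded state's stability;
  mechanisms that also change folding (inbound) rates or FRET values of
  states are out of scope.
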