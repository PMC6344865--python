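# Methods

## Scope and model

The package analyses single-molecule FRET data of a two-/few-state nucleic
acid (a DNA hairpin) in two acquisition modes and provides a generator that
emulates both from a declared ground truth.

Conformational dynamics are modeled as a continuous-time Markov chain
(`KineticScheme`): state *i* carries a Gaussian FRET emission (mean `e_mean`,
width `e_sd`) and nonnegative transition rates `rates[i][j]` (s⁻¹). Dwell
times in state *i* are exponential with mean 1/Σ_j rates[i][j]; the
equilibrium occupancies are the stationary distribution of the chain.

Thermodynamics enter through the pressure dependence of the unfolding
equilibrium constant, ln K_eq(p) = ln K_eq(p_ref) − ΔV°·(p − p_ref)/(RT),
with ΔV° the closed→open partial-molar-volume change (cm³ mol⁻¹),
R = 8.314 J mol⁻¹ K⁻¹, pressures stored in bar (1 bar = 10⁵ Pa exactly) and
converted to Pa internally.

## Synthetic-data generator

`simulate_state_path` is an exact Gillespie sampler; the initial state is
drawn from the stationary distribution so traces are equilibrium samples
from t = 0. A state with zero exit rate absorbs for the remaining duration.

`render_trace` (immobilized mode) draws, per 1-ms bin, an apparent FRET
value E\* as the occupancy-weighted mean of truncated-Gaussian draws
(exact inverse-CDF truncation to [0, 1]) around the occupied states' means;
the detected total is Poisson(brightness), split Binomial(N, E\*) into
acceptor and donor. The γ distortion is applied by dividing donor counts by
γ and rounding, so the published estimator E = n_A/(n_A + γ n_D) is exactly
unbiased for E\* — this matches the estimator's algebra, unlike binomial
thinning. Independent Poisson backgrounds are added per channel.

`simulate_bursts` (diffusing mode) treats each transit as static in one
state: the diffusion time (≈ the 1-ms bin) is two orders of magnitude below
the mean dwell at the hairpin's rates, so intra-burst switching is
negligible (an `allow_switching` flag samples a within-burst path for
robustness studies). Burst totals are Poisson(mean 100) truncated below at a
20-photon detection floor; neither the burst-size distribution nor the
numeric detection threshold is a measured quantity, so both are calibration
choices. Donor-only and acceptor-only contaminant species (default 5% each,
a typical labeling impurity level) are injected with, respectively, E ≈ 0
plus leakage noise and ~5% donor-excitation crosstalk; every burst carries a
direct-acceptor-excitation count matched in rate to the donor-excitation
signal, which centres the dual-labeled stoichiometry near 0.5.

All randomness flows from one integer master seed through
`np.random.SeedSequence` spawning; identical seeds give bit-identical
output.

What the generator does **not** emulate: diffusion paths through a confocal
point-spread function (burst-size/ duration correlations), triplet blinking,
photobleaching, spectral crosstalk beyond the fixed γ, and detector
afterpulsing. Passing recovery tests therefore demonstrates correctness of
the analysis chain under ideal photon statistics, not robustness to every
instrument artifact.

## Burst pipeline

Bursts are maximal runs of consecutive 1-ms bins whose donor+acceptor sum
exceeds a threshold; merging runs prevents double-counting a transit that
straddles a bin boundary. The default threshold is background mean +
10·√background (Poisson false positives negligible), overridable by an
absolute count. Stoichiometry S = (n_D + n_A)/(n_D + n_A + n_A,direct) is
near 1 for donor-only and near 0 for acceptor-only species; the default
dual-labeled window is (0.3, 0.7). E values are clamped to [0, 1] after γ
correction (shot noise on the rounded correction can stray marginally
outside); clamping is logged. Histograms use 50 bins on [0, 1] by default.

## Histogram deconvolution

The normalized E-histogram is fitted with k Gaussians (k chosen by the
analyst per condition) by bounded nonlinear least squares — amplitude, mean
and width per component, means in [0, 1], widths in [0.01, 0.5] — with 10
restarts from jittered density-quantile initializations. Component areas,
renormalized to sum to one, are the weights; two components converging onto
one mean (within 0.02) trigger a refit at k−1. State fractions follow the
area rule: components with mean below the open/closed boundary (default
0.45, the midpoint of the ≈0.3 and ≈0.8 peaks) count as open, the rest as
closed, with per-component overrides for conditions where one conformational
state carries a bimodal FRET distribution. An EM fit on the raw E samples
(sklearn `GaussianMixture`) is retained as an independent route; both must
agree on fractions within 0.03 (tested).

`fit_volume` regresses ln K_eq on pressure (unweighted OLS, matching the
plain linear fits customary for this quantity; a variance-weighted option
exists but is off by default) and reports ΔV° = −slope·RT with its standard
error. Points with K_eq ≤ 0 are excluded and counted. T defaults to
298.15 K.

## Trace kinetics

Per-bin E series use the γ-corrected estimator; empty bins carry the
previous value and are flagged, and a trace with >20% empty bins is
rejected. The hidden Markov model has Gaussian emissions and is trained by
maximum-likelihood Baum–Welch jointly across all molecules (shared
parameters, per-trace forward–backward with Rabiner scaling, numba
kernels). This replaces the variational-Bayes machinery of ebFRET-style
tools with a first-principles estimator whose contract — state count and
rate recovery on synthetic data — is tested directly; VB priors would
otherwise be unconstrained free parameters. Model order is selected over
k = 1..4 by minimum BIC with p = (k−1) + k(k−1) + 2k parameters.

Two degeneracy rules guard the selection:

* a state occupying <1% of bins is starved and cannot be kinetically
  analysed;
* two states whose means are closer than half their combined emission width
  (floor 0.02) are one conformational state split in two — in practice EM
  uses such splits to absorb the mild non-Gaussianity of photon noise
  (truncation skew, mid-transition bins), and BIC's penalty alone does not
  prevent this at multi-million-bin sample sizes.

Either condition triggers a logged refit at k−1; the checks also run during
EM (from iteration 10) so overfit candidates terminate early. Numerical
choices: quantile-based initial means with jittered restarts (default 2),
diagonal-0.98 initial transitions, emission-width floor 10⁻³ (keeps EM
stable on noiseless data), relative log-likelihood tolerance 10⁻⁶, at most
60 iterations, k = 1 in closed form. An EM likelihood decrease beyond
round-off aborts with diagnostics. Viterbi ties break toward the lower-E
state, deterministically.

Viterbi runs of constant state give dwell times (multiples of the bin
width). The first and last run of every trace are censored — truncated by
the observation window — and excluded from rate estimation; dwells shorter
than 2 bins are retained (no minimum-dwell filter; a configurable filter
exists since fast photophysics is out of scope). Each state's uncensored
dwells are fitted as N(≤t) = N_tot(1 − exp(−t/τ)) on the cumulative count
(N_tot fixed at the observed count), cross-checked against the
maximum-likelihood estimator (the sample mean); >10% disagreement flags
non-exponential dwells. Rates are exit rates k = 1/τ aggregating all
destinations; a secondary per-destination breakdown distributes each exit
rate over the observed transition counts. Viscosity correction multiplies
rates by η_sample/η_buffer (dwells by the reciprocal, so k·τ is invariant);
η_buffer defaults to 0.89 mPa·s (water/dilute buffer at 25 °C) and is
recorded in every rate table.

## Study conditions used by the tests and drivers

* Two-state scheme: k_f = 7.5, k_u = 3.13 s⁻¹; emissions 0.3/0.8, width
  0.07; 30 traces × 120 s, 1-ms bins, brightness 500 photons/bin (chosen so
  total per-bin E noise ≈ the 0.07 emission width; immobilized count rates
  are instrument-specific), background 2 photons/bin/channel.
* Three-state scheme: emissions 0.17/0.38/0.65, exit rates
  11.5/18.3/18.4 s⁻¹. The branching of each state's exits is not separately
  published; the default routes 80% of open- and partial-state exits to the
  closed state (occasional open↔partial transitions) and splits closed-state
  exits evenly, matching the qualitative transition pattern of three-state
  hairpin dynamics. Recovery of the aggregated exit rates is insensitive to
  this choice. 20 traces × 60 s keep the experiment inside a desktop-scale
  budget while providing ≳5000 dwells per state.
* Pressure series: 6 pressures (1, 200, 400, 600, 800, 1000 bar), 5000
  bursts each, mean burst size 100 photons, K_eq(1 bar) = 0.42 — the
  ambient-pressure equilibrium implied by the two-state rates
  (3.13/7.5 ≈ 0.42); the same reference is reused for every ΔV° condition
  since condition-specific ambient constants are not separately specified.
  ΔV° ground truths: −17.7 (neat buffer), −7.8 (TMAO), −29.5 (urea),
  −6.6 cm³ mol⁻¹ (Ficoll).

## Known limitations

* Recovered ΔV° carries a small negative bias (≈0.3–0.6 cm³ mol⁻¹ at the
  default conditions) from residual overlap of the Gaussian peaks and E
  clamping at the domain edges; it is well inside the recovery tolerance
  and vanishes in the noiseless limit.
* Exit-rate estimates for fast states (mean dwell ≲ 60 bins) are biased by
  a few percent by missed sub-bin excursions; at the hairpin's rates this
  stays within the stated tolerances.
* The HMM assumes shared emission parameters across molecules (global fit);
  a per-molecule option exists but static molecule-to-molecule heterogeneity
  is not modeled.
* BIC model selection is only trusted together with the degeneracy rules
  above; with strongly non-Gaussian emissions (e.g. heavy blinking) it
  would require a dedicated photophysics model.
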