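# hpfret

Single-molecule FRET analysis of DNA-hairpin conformational dynamics:
pressure-dependent burst analysis yields the **transition volume** of
unfolding, and hidden-Markov idealization of immobilized-molecule time traces
yields **folding/unfolding rate constants**. A synthetic-data generator
emulates both acquisition modes from a fully specified kinetic and
thermodynamic ground truth, so every stage of the analysis is testable
end-to-end by parameter recovery — no instrument data required.

## Who this is for

Biophysicists analysing confocal smFRET data of two- (or few-) state systems
such as DNA hairpins: a donor/acceptor dye pair reports the open (unfolded,
low FRET, E ≈ 0.3) versus closed (folded, high FRET, E ≈ 0.8) conformation.
Two experimental modes are covered:

* **Freely diffusing (burst) mode** — molecules transit the confocal volume,
  each transit producing a photon burst. Per-burst FRET efficiencies are
  estimated as E = n_A/(n_A + γ·n_D) (γ = 0.88 corrects unequal quantum
  yields/detection efficiencies), filtered by PIE stoichiometry to keep only
  dual-labeled molecules, histogrammed, and deconvolved into Gaussian peaks.
  Peak areas give state fractions, F_open and F_closed = 1 − F_open.
* **Immobilized mode** — surface-tethered molecules observed for minutes.
  The per-bin E time series is idealized with a Gaussian-emission HMM
  (Baum–Welch, BIC model selection), Viterbi decoding yields dwell times,
  and single-exponential fits to cumulative dwell-time distributions give
  rate constants k = 1/τ, optionally viscosity-corrected by
  k_corr = k·(η_sample/η_buffer).

## The model

A hairpin with unfolding equilibrium constant K_eq = F_open/F_closed obeys

    (∂ ln K_eq / ∂p)_T = −ΔV° / (RT)

so the transition volume ΔV° (cm³ mol⁻¹) is read off an ordinary
least-squares fit of ln K_eq against pressure (1–1000 bar). Conformational
dynamics follow a continuous-time Markov chain whose exit rates are the
folding/unfolding rate constants; dwell times in each state are exponential
with mean 1/(exit rate).

## Worked example

```python
import hpfret as hp
from hpfret.pipeline import DeltaVConfig, run_deltav_pipeline

scheme = hp.two_state_scheme(k_fold=7.5, k_unfold=3.13)   # s^-1
truth = hp.ThermoGroundTruth(delta_v=-17.7, keq_ref=0.42)  # cm^3/mol at 1 bar
vfit, points = run_deltav_pipeline(truth, scheme, DeltaVConfig(seed=11))
print(vfit.delta_v)
```

This simulates 5000 bursts at each of six pressures (1–1000 bar) from the
ground truth, runs the full burst pipeline and recovers ΔV° ≈ −18 cm³ mol⁻¹
(the exact value varies with the seed; the noiseless limit is exact).

The numbered drivers under `analysis/` run the complete studies and write
tab-separated tables under `results/`:

```text
$ python analysis/01_pressure_volumes.py
   neat buffer: truth   -17.7  recovered  -18.29 +/- 0.47 cm^3/mol
      1 M TMAO: truth    -7.8  recovered   -8.46 +/- 0.50 cm^3/mol
      1 M urea: truth   -29.5  recovered  -29.93 +/- 0.67 cm^3/mol
 20 wt% Ficoll: truth    -6.6  recovered   -7.22 +/- 0.33 cm^3/mol

$ python analysis/02_two_state_rates.py
k_f = 7.374 s^-1 (truth 7.5), k_u = 3.115 s^-1 (truth 3.13)
BIC-selected state counts over seeds: [2, 2, 2, 2, 2, 2, 2, 2, 2, 2]

$ python analysis/03_three_state_kinetics.py
BIC selected k = 3 (truth 3); means [0.175 0.382 0.648]
```

Each "recovered" number is the pipeline's estimate from synthetic data
generated with the quoted truth: agreement demonstrates that the analysis is
unbiased at realistic photon counts, trace lengths and burst numbers.

A small command-line interface mirrors the library
(`hpfret simulate-trace|simulate-bursts|deltav|kinetics`, see `hpfret --help`);
scheme files are versioned YAML, traces and burst tables plain TSV.

## Layout

```text
src/hpfret/      library: scheme, simulate, bursts, mixture, thermo,
                 kinetics (+ numba HMM kernels), io, pipeline, cli
analysis/        numbered narrative drivers writing results/
tests/           pytest suite (unit, property and end-to-end recovery tests)
docs/methods.md  model, assumptions, parameter choices, limitations
```
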