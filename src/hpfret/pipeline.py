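"""End-to-end pipelines tying the stages together.

Two chains mirror the two acquisition modes:

* diffusing: simulate (or load) bursts per pressure -> stoichiometry filter ->
  E-histogram -> Gaussian deconvolution -> F_open/F_closed -> Keq ->
  ln Keq vs p regression -> transition volume;
* immobilized: simulate (or load) traces -> per-bin E series -> HMM (BIC) ->
  Viterbi dwells -> cumulative exponential fits -> rate constants, optionally
  viscosity-corrected.

Every stage consumes sub-seeds derived from one master seed, and the report
records the effective value of every parameter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import __version__
from .bursts import (
    DEFAULT_GAMMA,
    DEFAULT_N_BINS,
    DEFAULT_S_WINDOW,
    filter_and_histogram,
)
from .errors import ConfigError, NumericalError
from .kinetics import (
    ETA_BUFFER_DEFAULT,
    fit_hmm,
    fret_series,
    rates_from_dwells,
    viterbi_dwells,
)
from .mixture import DEFAULT_BOUNDARY, assign_and_fractions, fit_mixture
from .scheme import AcquisitionConfig, KineticScheme, ThermoGroundTruth
from .simulate import (
    pressure_series,
    render_trace,
    simulate_bursts,
    simulate_state_path,
)
from .thermo import VolumeFit, fit_volume, pressure_point


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic independent sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class DeltaVConfig:
    """Parameters of the diffusing-mode (transition volume) pipeline."""

    pressures: tuple[float, ...] = (1.0, 200.0, 400.0, 600.0, 800.0, 1000.0)
    n_bursts: int = 5000
    burst_size_mean: float = 100.0
    gamma: float = DEFAULT_GAMMA
    s_window: tuple[float, float] = DEFAULT_S_WINDOW
    n_bins: int = DEFAULT_N_BINS
    boundary: float = DEFAULT_BOUNDARY
    mixture_k: int = 2
    temperature: float = 298.15
    seed: int = 0


def run_deltav_pipeline(
    truth: ThermoGroundTruth,
    scheme: KineticScheme,
    config: DeltaVConfig | None = None,
) -> tuple[VolumeFit, list]:
    """Simulate bursts along a pressure series and recover the transition volume.

    Returns the volume fit plus the per-pressure points (fractions and Keq).
    """
    cfg = config or DeltaVConfig()
    if scheme.n_states != 2:
        raise ConfigError("the transition-volume pipeline assumes 2 states")
    fracs = pressure_series(truth, cfg.pressures)
    acq = AcquisitionConfig(gamma=cfg.gamma)
    seeds = spawn_seeds(cfg.seed, len(fracs))
    points = []
    for (p, f_open, f_closed), sub in zip(fracs, seeds):
        # State 0 is open (low E), state 1 closed, as in two_state_scheme.
        bursts = simulate_bursts(
            populations=[f_open, f_closed],
            scheme=scheme,
            n_bursts=cfg.n_bursts,
            burst_size_mean=cfg.burst_size_mean,
            cfg=acq,
            seed=sub,
        )
        hist = filter_and_histogram(
            bursts,
            s_min=cfg.s_window[0],
            s_max=cfg.s_window[1],
            gamma=cfg.gamma,
            n_bins=cfg.n_bins,
        )
        fit = fit_mixture(hist, k=cfg.mixture_k, seed=sub)
        fractions = assign_and_fractions(fit, boundary=cfg.boundary)
        points.append(pressure_point(p, fractions))
    try:
        vfit = fit_volume(points, temperature=cfg.temperature)
    except ValueError as exc:
        raise NumericalError(str(exc)) from exc
    return vfit, points


@dataclass
class KineticsConfig:
    """Parameters of the immobilized-mode (rate constant) pipeline."""

    n_traces: int = 30
    trace_duration: float = 120.0
    brightness: float = 500.0
    background: float = 2.0
    gamma: float = DEFAULT_GAMMA
    k_range: tuple[int, ...] = (1, 2, 3, 4)
    restarts: int = 2
    eta_sample: float | None = None
    eta_buffer: float = ETA_BUFFER_DEFAULT
    seed: int = 0


def run_kinetics_pipeline(
    scheme: KineticScheme,
    labeling: Sequence[str] | None = None,
    config: KineticsConfig | None = None,
):
    """Simulate immobilized traces and recover rate constants end to end.

    Returns (RateTable, StateModel).  ``labeling`` names the recovered HMM
    states in ascending-mean order; by default the scheme's labels sorted by
    their emission means are used (valid when BIC recovers the true k).
    """
    cfg = config or KineticsConfig()
    acq = AcquisitionConfig(
        brightness=cfg.brightness,
        background_d=cfg.background,
        background_a=cfg.background,
        gamma=cfg.gamma,
        contaminant_fractions=(0.0, 0.0),
    )
    seeds = spawn_seeds(cfg.seed, 2 * cfg.n_traces + 1)
    series = []
    for i in range(cfg.n_traces):
        traj = simulate_state_path(scheme, cfg.trace_duration, seeds[2 * i])
        trace = render_trace(traj, scheme, acq, seed=seeds[2 * i + 1])
        series.append(fret_series(trace, gamma=cfg.gamma, molecule_id=str(i)))
    model = fit_hmm(
        series, k_range=cfg.k_range, restarts=cfg.restarts, seed=seeds[-1]
    )
    dwells = viterbi_dwells(model, series)
    if labeling is None:
        order = np.argsort(scheme.e_means)
        if model.k == scheme.n_states:
            labeling = [scheme.states[i].label for i in order]
        else:
            labeling = [f"state{i + 1}" for i in range(model.k)]
    rates = rates_from_dwells(
        dwells, labeling, eta_sample=cfg.eta_sample, eta_buffer=cfg.eta_buffer
    )
    return rates, model


@dataclass
class AnalysisReport:
    """Machine-readable summary of a pipeline run (JSON round-trippable)."""

    mode: str
    parameters: dict
    results: dict
    seed: int
    software_version: str = __version__
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.config_hash:
            payload = json.dumps(
                {"mode": self.mode, "parameters": self.parameters, "seed": self.seed},
                sort_keys=True,
            )
            self.config_hash = hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def deltav_report(
    truth: ThermoGroundTruth,
    scheme: KineticScheme,
    config: DeltaVConfig | None = None,
) -> AnalysisReport:
    cfg = config or DeltaVConfig()
    vfit, points = run_deltav_pipeline(truth, scheme, cfg)
    return AnalysisReport(
        mode="deltav",
        parameters={**asdict(cfg), "truth_delta_v": truth.delta_v},
        results={
            "delta_v_cm3_mol": vfit.delta_v,
            "delta_v_se_cm3_mol": vfit.delta_v_se,
            "n_points": vfit.n_points,
            "points": [
                {
                    "pressure_bar": pt.pressure,
                    "f_open": pt.fractions.f_open,
                    "f_closed": pt.fractions.f_closed,
                    "keq": pt.keq,
                }
                for pt in points
            ],
        },
        seed=cfg.seed,
    )


def kinetics_report(
    scheme: KineticScheme,
    config: KineticsConfig | None = None,
) -> AnalysisReport:
    cfg = config or KineticsConfig()
    rates, model = run_kinetics_pipeline(scheme, config=cfg)
    return AnalysisReport(
        mode="kinetics",
        parameters=asdict(cfg),
        results={
            "k_selected": model.k,
            "bic": model.bic,
            "means": list(model.means),
            "sds": list(model.sds),
            "rates": json.loads(rates.table.to_json(orient="index")),
            "eta_buffer_mPas": rates.eta_buffer,
            "eta_sample_mPas": rates.eta_sample,
        },
        seed=cfg.seed,
    )
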