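"""Synthetic-data generators for both smFRET acquisition modes.

Ground truth is a :class:`~hpfret.scheme.KineticScheme` (conformational states
with Gaussian FRET emissions and a rate matrix) plus, for pressure series, a
:class:`~hpfret.scheme.ThermoGroundTruth`.  Three generators cover the study
conditions:

* :func:`simulate_state_path` — exact (Gillespie) sampling of the
  continuous-time Markov chain;
* :func:`render_trace` — the immobilized acquisition: per-bin photon counts
  with shot noise, gamma distortion and background, from a state path;
* :func:`simulate_bursts` — the freely-diffusing acquisition: per-transit
  photon bursts with donor-only / acceptor-only contaminant species and a
  direct-acceptor-excitation count for stoichiometry filtering.

All randomness flows from one integer master seed via ``np.random.SeedSequence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .bursts import BinnedDualTrace
from .scheme import (
    AcquisitionConfig,
    KineticScheme,
    ThermoGroundTruth,
    Trajectory,
)

logger = logging.getLogger(__name__)

#: Minimum photons for a simulated burst (detection-floor truncation).
BURST_FLOOR = 20

#: Sentinel state indices for contaminant bursts.
DONOR_ONLY = -1
ACCEPTOR_ONLY = -2


def simulate_state_path(
    scheme: KineticScheme, duration: float, seed: int | np.random.Generator
) -> Trajectory:
    """Exact stochastic simulation of the kinetic scheme for ``duration`` s.

    In state i the dwell is Exponential(sum_j rates[i][j]) and the successor
    is drawn with probability rates[i][j] / sum_j.  The initial state is drawn
    from the stationary distribution so that long traces are equilibrium
    samples from the start.  A state with zero exit rate absorbs: the path
    ends with a single segment spanning the remaining time.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    exit_rates = scheme.exit_rates()
    pi = scheme.stationary_distribution()
    state = int(rng.choice(scheme.n_states, p=pi))

    states: list[int] = []
    starts: list[float] = []
    ends: list[float] = []
    t = 0.0
    while t < duration:
        lam = exit_rates[state]
        if lam <= 0.0:
            dwell = duration - t
        else:
            dwell = rng.exponential(1.0 / lam)
        t_end = min(t + dwell, duration)
        states.append(state)
        starts.append(t)
        ends.append(t_end)
        t = t_end
        if t >= duration:
            break
        probs = scheme.rates[state] / lam
        state = int(rng.choice(scheme.n_states, p=probs))
    ends[-1] = duration
    return Trajectory(
        states=np.array(states),
        starts=np.array(starts),
        ends=np.array(ends),
        duration=duration,
    )


def _truncated_gaussian_e(
    means: np.ndarray, sds: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-state truncated-Gaussian FRET draws, shape (size, n_states)."""
    n_states = len(means)
    draws = np.empty((size, n_states))
    for k in range(n_states):
        if sds[k] == 0.0:
            draws[:, k] = means[k]
            continue
        # Exact truncated normal via inverse-CDF sampling on [0, 1].
        lo = ndtr((0.0 - means[k]) / sds[k])
        hi = ndtr((1.0 - means[k]) / sds[k])
        u = rng.uniform(lo, hi, size=size)
        draws[:, k] = means[k] + sds[k] * ndtri(u)
    return draws


def _partition_photons(
    totals: np.ndarray, e_app: np.ndarray, gamma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split photon totals into (donor, acceptor) counts with gamma distortion.

    Acceptor ~ Binomial(N, E); the donor share is divided by gamma and rounded,
    so the gamma-corrected estimator E = nA / (nA + gamma nD) is unbiased for
    the generative E.
    """
    acceptor = rng.binomial(totals, e_app)
    donor = np.rint((totals - acceptor) / gamma).astype(np.int64)
    return donor, acceptor


def render_trace(
    traj: Trajectory,
    scheme: KineticScheme,
    cfg: AcquisitionConfig,
    seed: int | np.random.Generator | None = None,
) -> BinnedDualTrace:
    """Render a state path into a binned dual-channel photon trace.

    Per bin the apparent FRET ``E*`` is the occupancy-weighted mean of
    truncated-Gaussian draws around each occupied state's e_mean; the total
    detected signal is Poisson(brightness), split binomially into acceptor
    and donor with gamma distortion; independent Poisson backgrounds are
    added per channel (including the direct-acceptor channel).
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    if traj.duration < cfg.bin_width:
        raise ValueError("trajectory shorter than one bin")
    occ = traj.bin_occupancy(cfg.bin_width, scheme.n_states)
    n_bins = occ.shape[0]
    if n_bins * cfg.bin_width < traj.duration - 1e-12:
        logger.info(
            "dropped trailing partial bin (%.3g s of %.3g s)",
            traj.duration - n_bins * cfg.bin_width,
            traj.duration,
        )
    draws = _truncated_gaussian_e(scheme.e_means, scheme.e_sds, n_bins, rng)
    e_app = np.clip((occ * draws).sum(axis=1), 0.0, 1.0)

    totals = rng.poisson(cfg.brightness, size=n_bins)
    donor, acceptor = _partition_photons(totals, e_app, cfg.gamma, rng)
    donor = donor + rng.poisson(cfg.background_d, size=n_bins)
    acceptor = acceptor + rng.poisson(cfg.background_a, size=n_bins)
    direct = rng.poisson(cfg.background_a, size=n_bins)
    return BinnedDualTrace(
        bin_width=cfg.bin_width,
        donor=donor,
        acceptor=acceptor,
        acceptor_direct=direct,
        metadata={"gamma": cfg.gamma},
    )


@dataclass(frozen=True)
class BurstSet:
    """Simulated per-burst photon records (freely-diffusing mode).

    ``true_state`` is the generative state index, or the sentinels
    DONOR_ONLY (-1) / ACCEPTOR_ONLY (-2) for contaminant species.
    """

    n_d: np.ndarray
    n_a: np.ndarray
    n_a_direct: np.ndarray
    true_state: np.ndarray
    gamma: float

    def __len__(self) -> int:
        return len(self.n_d)


def simulate_bursts(
    populations: Sequence[float],
    scheme: KineticScheme,
    n_bursts: int,
    burst_size_mean: float,
    cfg: AcquisitionConfig,
    seed: int | np.random.Generator | None = None,
    allow_switching: bool = False,
) -> BurstSet:
    """Draw photon bursts from a mixture of conformational states.

    Each transit is treated as static in one state (transit time ~ 1 ms is
    far below the mean dwell at the hairpin's rates); ``allow_switching``
    instead samples a short state path per burst and uses its
    occupancy-weighted E, for robustness studies.  Burst totals are
    Poisson(burst_size_mean) truncated below at BURST_FLOOR photons.
    Donor-only and acceptor-only contaminant bursts are injected at
    ``cfg.contaminant_fractions``; every burst carries a direct-acceptor
    count so stoichiometry can separate the species.
    """
    weights = np.asarray(populations, dtype=float)
    if weights.size == 0 or np.all(weights == 0):
        raise ValueError("no populated states")
    if np.any(weights < 0):
        raise ValueError("populations must be >= 0")
    if weights.size != scheme.n_states:
        raise ValueError("populations length must match scheme states")
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    weights = weights / weights.sum()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    f_donly, f_aonly = cfg.contaminant_fractions
    kind = rng.choice(
        3, size=n_bursts, p=[1.0 - f_donly - f_aonly, f_donly, f_aonly]
    )
    state = np.where(
        kind == 0,
        rng.choice(scheme.n_states, size=n_bursts, p=weights),
        np.where(kind == 1, DONOR_ONLY, ACCEPTOR_ONLY),
    )

    # Burst sizes: Poisson truncated below at the detection floor.
    totals = rng.poisson(burst_size_mean, size=n_bursts)
    while np.any(totals < BURST_FLOOR):
        redo = totals < BURST_FLOOR
        totals[redo] = rng.poisson(burst_size_mean, size=int(redo.sum()))

    # Apparent E per burst.
    e_app = np.empty(n_bursts)
    dual = kind == 0
    if allow_switching:
        for i in np.flatnonzero(dual):
            traj = simulate_state_path(scheme, cfg.bin_width, rng)
            occ = traj.occupancy_fractions(scheme.n_states)
            draw = _truncated_gaussian_e(scheme.e_means, scheme.e_sds, 1, rng)[0]
            e_app[i] = float(np.clip(occ @ draw, 0.0, 1.0))
    else:
        draws = _truncated_gaussian_e(scheme.e_means, scheme.e_sds, n_bursts, rng)
        e_app[dual] = draws[dual, state[dual]]
    # Donor-only: no acceptor, E near 0 up to spectral leakage.
    e_app[kind == 1] = np.clip(rng.normal(0.03, 0.02, size=int((kind == 1).sum())), 0.0, 0.2)
    e_app[kind == 2] = 0.5  # placeholder; acceptor-only totals are rescaled below

    # Acceptor-only species barely emit under donor excitation.
    totals = np.asarray(totals, dtype=np.int64)
    aonly = kind == 2
    totals[aonly] = rng.poisson(0.05 * burst_size_mean, size=int(aonly.sum()))

    donor, acceptor = _partition_photons(totals, e_app, cfg.gamma, rng)

    # Direct acceptor excitation: matched to the donor-excitation rate for
    # dual- and acceptor-labeled species, background-level for donor-only.
    direct = np.where(
        kind == 1,
        rng.poisson(cfg.background_a, size=n_bursts),
        rng.poisson(burst_size_mean, size=n_bursts),
    )
    return BurstSet(
        n_d=donor,
        n_a=acceptor,
        n_a_direct=np.asarray(direct, dtype=np.int64),
        true_state=state,
        gamma=cfg.gamma,
    )


def bursts_to_trace(
    burst_set: BurstSet,
    cfg: AcquisitionConfig,
    spacing_bins: int = 5,
    seed: int | np.random.Generator | None = None,
) -> BinnedDualTrace:
    """Embed simulated bursts into a background trace, one burst per bin.

    Bursts are separated by ``spacing_bins`` background-only bins so that
    threshold-based burst detection can be exercised end to end.
    """
    if spacing_bins < 1:
        raise ValueError("spacing_bins must be >= 1")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    n = len(burst_set)
    n_bins = n * (spacing_bins + 1) + spacing_bins
    donor = rng.poisson(cfg.background_d, size=n_bins)
    acceptor = rng.poisson(cfg.background_a, size=n_bins)
    direct = rng.poisson(cfg.background_a, size=n_bins)
    idx = spacing_bins + np.arange(n) * (spacing_bins + 1)
    donor[idx] += burst_set.n_d
    acceptor[idx] += burst_set.n_a
    direct[idx] += burst_set.n_a_direct
    return BinnedDualTrace(
        bin_width=cfg.bin_width,
        donor=donor,
        acceptor=acceptor,
        acceptor_direct=direct,
        metadata={"gamma": burst_set.gamma},
    )


class PressureFractions(NamedTuple):
    pressure: float  # bar
    f_open: float
    f_closed: float


def pressure_series(
    truth: ThermoGroundTruth, pressures: Sequence[float]
) -> list[PressureFractions]:
    """Equilibrium open/closed fractions along a pressure series.

    Keq(p) follows the exact log-linear law with slope -dV/(R T);
    F_open = Keq / (1 + Keq).
    """
    pressures = list(pressures)
    if len(pressures) == 0:
        raise ValueError("pressures must be nonempty")
    if any(p < 1.0 for p in pressures):
        raise ValueError("pressures must each be >= 1 bar")
    out = []
    for p in pressures:
        keq = truth.keq(p)
        f_open = keq / (1.0 + keq)
        out.append(PressureFractions(p, f_open, 1.0 - f_open))
    return out
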