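"""Immobilized-molecule kinetics: HMM idealization, dwell times and rates.

The FRET-efficiency time series of a surface-attached hairpin is idealized
with a Gaussian-emission hidden Markov model trained by Baum-Welch jointly
over all molecules (shared parameters); the state count is selected by BIC.
Viterbi decoding yields runs of constant state whose durations are the dwell
times; the first and last run of every trace are censored (truncated by the
observation window) and excluded from rate estimation.  Cumulative dwell-time
distributions are fitted with single exponentials N(<=t) = N (1 - exp(-t/tau))
and rate constants reported as k = 1/tau, optionally viscosity-corrected by
k_corr = k * eta_sample / eta_buffer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import _hmm
from .bursts import BinnedDualTrace, DEFAULT_GAMMA

logger = logging.getLogger(__name__)

#: Water / dilute buffer viscosity at 25 C, mPa s.
ETA_BUFFER_DEFAULT = 0.89

MIN_SERIES_BINS = 10
MIN_DWELLS = 10


@dataclass(frozen=True)
class FretSeries:
    """Per-bin FRET efficiencies of one molecule."""

    e: np.ndarray
    bin_width: float
    molecule_id: str = ""
    flagged: np.ndarray | None = None  # bins whose E was carried forward

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "e", e)
        if len(e) < MIN_SERIES_BINS:
            raise ValueError(f"series must have >= {MIN_SERIES_BINS} bins")
        if not np.all(np.isfinite(e)):
            raise ValueError("E values must be finite")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def fret_series(trace: BinnedDualTrace, gamma: float = DEFAULT_GAMMA,
                molecule_id: str = "") -> FretSeries:
    """Per-bin E = nA / (nA + gamma nD) from a binned dual-channel trace.

    Bins with zero total carry the previous bin's value and are flagged;
    more than 20% such bins means the trace is too dim to idealize.
    """
    total = trace.donor + trace.acceptor
    zero = total == 0
    if zero.mean() > 0.20:
        raise ValueError("trace too dim: > 20% of bins have no photons")
    with np.errstate(invalid="ignore", divide="ignore"):
        e = trace.acceptor / (trace.acceptor + gamma * trace.donor)
    if np.any(zero):
        idx = np.where(~zero, np.arange(len(e)), -1)
        np.maximum.accumulate(idx, out=idx)
        first_valid = int(np.argmax(~zero))
        idx[idx < 0] = first_valid
        e = e[idx]
    return FretSeries(
        e=e, bin_width=trace.bin_width, molecule_id=molecule_id, flagged=zero
    )


@dataclass(frozen=True)
class StateModel:
    """Trained Gaussian-emission HMM (means sorted ascending)."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    trans: np.ndarray  # per-bin transition probabilities, row stochastic
    initial: np.ndarray
    log_likelihood: float
    bic: float
    n_obs: int

    def __post_init__(self) -> None:
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be > 0")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("means must be sorted ascending")


def _as_obs(series: Sequence[FretSeries] | FretSeries):
    if isinstance(series, FretSeries):
        series = [series]
    series = list(series)
    if not series:
        raise ValueError("no series supplied")
    bw = series[0].bin_width
    if any(abs(s.bin_width - bw) > 1e-12 for s in series):
        raise ValueError("all series must share one bin width")
    obs = np.concatenate([s.e for s in series])
    offsets = np.zeros(len(series) + 1, dtype=np.int64)
    np.cumsum([len(s.e) for s in series], out=offsets[1:])
    return series, obs, offsets, bw


def _n_params(k: int) -> int:
    return (k - 1) + k * (k - 1) + 2 * k


SD_FLOOR = 1e-3  # keeps EM stable on noiseless (zero-width) data


def _unresolvable(means: np.ndarray, sds: np.ndarray) -> bool:
    """True when two states are closer than half their combined emission width.

    Such a pair is one conformational state split in two (typically EM
    absorbing mild non-Gaussianity of the photon noise) and is treated as
    degenerate, like same-mean components in the histogram deconvolution.
    """
    order = np.argsort(means)
    m, s = means[order], sds[order]
    gaps = np.diff(m)
    widths = 0.5 * (s[:-1] + s[1:])
    return bool(np.any(gaps < np.maximum(0.02, widths)))


def _fit_single_k(
    obs: np.ndarray,
    offsets: np.ndarray,
    k: int,
    restarts: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best-of-restarts Baum-Welch for a fixed state count."""
    if k == 1:
        # Closed form: a single Gaussian, no dynamics to estimate.
        mean = float(np.mean(obs))
        sd = max(float(np.std(obs)), SD_FLOOR)
        ll = float(
            -0.5 * len(obs) * (1.0 + np.log(2.0 * np.pi * sd**2))
        )
        return (
            ll,
            np.array([mean]),
            np.array([sd]),
            np.ones((1, 1)),
            np.ones(1),
            np.ones(1),
        )
    qs = (np.arange(k) + 0.5) / k
    base_means = np.quantile(obs, qs)
    spread = max(float(np.std(obs)), 1e-3)
    best = None
    for r in range(max(restarts, 1)):
        if r == 0:
            means = base_means.copy()
        else:
            means = np.sort(base_means + rng.normal(0.0, 0.3 * spread, size=k))
        sds = np.full(k, max(spread / max(k, 2), 0.02))
        stay = 0.98
        trans = np.full((k, k), (1.0 - stay) / max(k - 1, 1))
        np.fill_diagonal(trans, stay)
        init = np.full(k, 1.0 / k)

        ll_prev = -np.inf
        occupancy = np.full(k, 1.0 / k)
        degenerate = False
        for it in range(max_iter):
            ll, init_acc, s0, s1, s2, xi = _hmm.em_step(
                obs, offsets, means, sds, trans, init
            )
            if ll < ll_prev - 1e-6 * max(1.0, abs(ll)):
                raise RuntimeError(
                    f"EM log-likelihood decreased ({ll_prev:.6g} -> {ll:.6g}) "
                    f"at iteration {it}, k={k}"
                )
            converged = ll - ll_prev < tol * max(1.0, abs(ll))
            ll_prev = ll
            # M-step
            s0 = np.maximum(s0, 1e-12)
            means = s1 / s0
            var = np.maximum(s2 / s0 - means**2, SD_FLOOR**2)
            sds = np.sqrt(var)
            row = xi.sum(axis=1, keepdims=True)
            trans = np.where(row > 0, xi / np.maximum(row, 1e-12), trans)
            trans = trans / trans.sum(axis=1, keepdims=True)
            init = init_acc / init_acc.sum()
            occupancy = s0 / s0.sum()
            if it >= 10 and (
                np.any(occupancy < 0.01) or _unresolvable(means, sds)
            ):
                # A starved or unresolvable state cannot recover; the caller
                # refits at k-1.
                degenerate = True
                break
            if converged and it > 2:
                break
        if best is None or ll_prev > best[0]:
            best = (ll_prev, means, sds, trans, init, occupancy)
        if degenerate:
            break  # further restarts of an overfit k waste cycles
    return best


def fit_hmm(
    series: Sequence[FretSeries] | FretSeries,
    k_range: Iterable[int] = (1, 2, 3, 4),
    restarts: int = 2,
    seed: int = 0,
    max_iter: int = 60,
    tol: float = 1e-6,
) -> StateModel:
    """Train Gaussian-emission HMMs over the pooled series and select k by BIC.

    Baum-Welch with shared parameters across molecules (per-trace
    forward-backward), multiple restarts from perturbed quantile-based
    initializations, deterministic for a fixed seed.  A state occupying
    < 1% of bins is degenerate: that candidate is refitted at k-1 (logged).
    """
    series, obs, offsets, _bw = _as_obs(series)
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 1 or k > 4 for k in k_range):
        raise ValueError("state counts must lie in 1..4")
    if len(obs) < 50 * max(k_range):
        raise ValueError("combined series too short for the requested k")
    rng = np.random.default_rng(seed)

    candidates: dict[int, tuple] = {}

    def fit_k(k: int):
        if k in candidates:
            return
        res = _fit_single_k(obs, offsets, k, restarts, rng, max_iter, tol)
        ll, means, sds, trans, init, occupancy = res
        if k > 1 and (np.any(occupancy < 0.01) or _unresolvable(means, sds)):
            logger.info(
                "k=%d has a degenerate state (occupancy %s, means %s); "
                "refitting at k=%d",
                k, occupancy, means, k - 1,
            )
            fit_k(k - 1)
            candidates[k] = None
            return
        candidates[k] = res

    for k in k_range:
        fit_k(k)

    best_model = None
    for k, res in candidates.items():
        if res is None:
            continue
        ll, means, sds, trans, init, _occ = res
        order = np.argsort(means)
        model = StateModel(
            k=k,
            means=means[order],
            sds=sds[order],
            trans=trans[np.ix_(order, order)],
            initial=init[order],
            log_likelihood=float(ll),
            bic=float(-2.0 * ll + _n_params(k) * np.log(len(obs))),
            n_obs=len(obs),
        )
        if best_model is None or model.bic < best_model.bic:
            best_model = model
    if best_model is None:
        raise RuntimeError("no HMM candidate converged")
    return best_model


def viterbi_path(model: StateModel, series: FretSeries) -> np.ndarray:
    """Most probable state sequence for one series (ties to the lower state)."""
    return _hmm.viterbi(
        series.e, model.means, model.sds, model.trans, model.initial
    )


@dataclass
class DwellSet:
    """Per-state dwell durations with censoring flags and transition counts."""

    durations: list[np.ndarray]  # seconds, one array per state
    censored: list[np.ndarray]  # parallel bool arrays
    transitions: np.ndarray  # (k, k) exit counts between consecutive runs
    bin_width: float

    @property
    def n_states(self) -> int:
        return len(self.durations)

    def uncensored(self, state: int) -> np.ndarray:
        return self.durations[state][~self.censored[state]]


def _runs(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a state path -> (states, lengths)."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(path)]])
    return path[starts], ends - starts


def viterbi_dwells(
    model: StateModel, series: Sequence[FretSeries] | FretSeries
) -> DwellSet:
    """Viterbi-decode traces and collect dwell times per state.

    The first and last run of every trace are flagged censored; transition
    counts are tallied from consecutive run pairs.
    """
    series, _obs, _off, bw = _as_obs(series)
    durations: list[list[float]] = [[] for _ in range(model.k)]
    censored: list[list[bool]] = [[] for _ in range(model.k)]
    transitions = np.zeros((model.k, model.k), dtype=np.int64)
    for s in series:
        path = viterbi_path(model, s)
        states, lengths = _runs(path)
        n_runs = len(states)
        for i, (st, ln) in enumerate(zip(states, lengths)):
            durations[st].append(ln * bw)
            censored[st].append(i == 0 or i == n_runs - 1)
        for a, b in zip(states[:-1], states[1:]):
            transitions[a, b] += 1
    return DwellSet(
        durations=[np.array(d) for d in durations],
        censored=[np.array(c, dtype=bool) for c in censored],
        transitions=transitions,
        bin_width=bw,
    )


def cumulative_exponential_fit(dwells: np.ndarray) -> tuple[float, float]:
    """Fit N(<=t) = N_tot (1 - exp(-t/tau)) to the cumulative dwell counts.

    Returns (tau, tau_se) in the dwells' time unit.  The fit is cross-checked
    against the maximum-likelihood estimator (the sample mean); disagreement
    beyond 10% raises a warning flagging non-exponential dwells.
    """
    dwells = np.sort(np.asarray(dwells, dtype=float))
    n = len(dwells)
    if n < MIN_DWELLS:
        raise ValueError(f"insufficient events: {n} < {MIN_DWELLS} dwells")
    counts = np.arange(1, n + 1, dtype=float)

    def model(t, tau):
        return n * (1.0 - np.exp(-t / tau))

    mean = float(dwells.mean())
    popt, pcov = curve_fit(
        model, dwells, counts, p0=[mean], bounds=(1e-12, np.inf), maxfev=10000
    )
    tau = float(popt[0])
    tau_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    if abs(tau - mean) > 0.10 * mean:
        warnings.warn(
            f"cumulative-fit tau ({tau:.4g}) and MLE mean ({mean:.4g}) "
            "disagree by > 10%: dwells may not be exponential",
            stacklevel=2,
        )
    return tau, tau_se


def viscosity_correct(
    value: float,
    eta_sample: float,
    eta_buffer: float = ETA_BUFFER_DEFAULT,
    kind: str = "rate",
) -> float:
    """Remove solvent-friction slowdown from a rate or dwell time.

    Rates are multiplied by eta_sample/eta_buffer; dwell times by the
    reciprocal, so k_corr * tau_corr == k * tau for any viscosity pair.
    """
    if eta_sample <= 0 or eta_buffer <= 0:
        raise ValueError("viscosities must be > 0")
    ratio = eta_sample / eta_buffer
    if kind == "rate":
        return value * ratio
    if kind == "dwell":
        return value / ratio
    raise ValueError("kind must be 'rate' or 'dwell'")


@dataclass
class RateTable:
    """Per-state dwell times and rate constants, raw and viscosity-corrected.

    ``table`` is indexed by state label with columns ``tau_s``, ``tau_se_s``,
    ``k_per_s``, ``n_dwells`` and, when viscosities are supplied,
    ``tau_corr_s`` and ``k_corr_per_s``.  ``transition_rates`` breaks each
    state's exit rate into per-destination rates via the observed transition
    counts.
    """

    table: pd.DataFrame
    transition_rates: pd.DataFrame | None = None
    eta_sample: float | None = None
    eta_buffer: float = ETA_BUFFER_DEFAULT

    def rate(self, label: str) -> float:
        return float(self.table.loc[label, "k_per_s"])

    def rate_corr(self, label: str) -> float:
        return float(self.table.loc[label, "k_corr_per_s"])


def rates_from_dwells(
    dwells: DwellSet,
    labeling: Sequence[str],
    eta_sample: float | None = None,
    eta_buffer: float = ETA_BUFFER_DEFAULT,
) -> RateTable:
    """Exit rates per labeled state from single-exponential dwell fits.

    ``labeling`` gives one label per HMM state in ascending-mean order, e.g.
    ("open", "closed") for the two-state hairpin — then k_f = 1/tau(open)
    and k_u = 1/tau(closed) — or ("state1", "state2", "state3") for the
    three-state schemes, where each k aggregates all outgoing transitions.
    Supplying ``eta_sample`` adds viscosity-corrected columns.
    """
    if len(labeling) != dwells.n_states:
        raise ValueError("labeling must name every state")
    if len(set(labeling)) != len(labeling):
        raise ValueError("state labels must be unique")
    rows = []
    for idx, label in enumerate(labeling):
        unc = dwells.uncensored(idx)
        tau, tau_se = cumulative_exponential_fit(unc)
        row = {
            "state_index": idx,
            "tau_s": tau,
            "tau_se_s": tau_se,
            "k_per_s": 1.0 / tau,
            "n_dwells": len(unc),
        }
        if eta_sample is not None:
            row["tau_corr_s"] = viscosity_correct(
                tau, eta_sample, eta_buffer, kind="dwell"
            )
            row["k_corr_per_s"] = viscosity_correct(
                1.0 / tau, eta_sample, eta_buffer, kind="rate"
            )
        rows.append(row)
    table = pd.DataFrame(rows, index=list(labeling))

    # Secondary breakdown: split each exit rate over destinations by counts.
    counts = dwells.transitions.astype(float)
    out = counts.sum(axis=1)
    trans_rows = []
    for i, src in enumerate(labeling):
        for j, dst in enumerate(labeling):
            if i == j or out[i] == 0:
                continue
            trans_rows.append(
                {
                    "from": src,
                    "to": dst,
                    "n": int(counts[i, j]),
                    "k_per_s": table.loc[src, "k_per_s"] * counts[i, j] / out[i],
                }
            )
    transition_rates = pd.DataFrame(trans_rows) if trans_rows else None
    return RateTable(
        table=table,
        transition_rates=transition_rates,
        eta_sample=eta_sample,
        eta_buffer=eta_buffer,
    )
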