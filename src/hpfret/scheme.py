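"""Kinetic and thermodynamic ground-truth descriptions of a FRET-labeled hairpin.

A :class:`KineticScheme` is a continuous-time Markov chain over conformational
states, each state carrying a Gaussian FRET-efficiency emission (mean and
width).  A :class:`ThermoGroundTruth` encodes the pressure dependence of the
closed-to-open equilibrium constant,

    ln Keq(p) = ln Keq(p_ref) - dV * (p - p_ref) / (R * T),

with dV the transition (partial molar volume) change upon unfolding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: 1 bar in Pa (exact).
BAR_TO_PA = 1.0e5

#: 1 cm^3 in m^3 (exact).
CM3_TO_M3 = 1.0e-6


@dataclass(frozen=True)
class StateSpec:
    """One conformational state: a label and its FRET emission parameters."""

    label: str
    e_mean: float
    e_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_mean <= 1.0:
            raise ValueError(f"e_mean must lie in [0, 1], got {self.e_mean}")
        if self.e_sd < 0.0:
            raise ValueError(f"e_sd must be >= 0, got {self.e_sd}")


@dataclass(frozen=True)
class KineticScheme:
    """States plus a nonnegative rate matrix (s^-1, diagonal zero)."""

    states: tuple[StateSpec, ...]
    rates: np.ndarray

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("at least one state required")
        means = [s.e_mean for s in self.states]
        if len(set(means)) != len(means):
            raise ValueError("state e_mean values must be distinct")
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        n = len(self.states)
        if rates.shape != (n, n):
            raise ValueError(f"rate matrix must be {n}x{n}, got {rates.shape}")
        if not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite")
        if np.any(rates < 0.0):
            raise ValueError("rates must be nonnegative")
        if np.any(np.diag(rates) != 0.0):
            raise ValueError("rate matrix diagonal must be zero")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    @property
    def e_means(self) -> np.ndarray:
        return np.array([s.e_mean for s in self.states])

    @property
    def e_sds(self) -> np.ndarray:
        return np.array([s.e_sd for s in self.states])

    def exit_rates(self) -> np.ndarray:
        """Total exit rate per state, sum_j rates[i][j] (s^-1)."""
        return self.rates.sum(axis=1)

    def stationary_distribution(self) -> np.ndarray:
        """Analytic stationary distribution of the chain (pi @ Q = 0)."""
        n = self.n_states
        if n == 1:
            return np.ones(1)
        q = self.rates - np.diag(self.exit_rates())
        # Append the normalization row and solve the overdetermined system.
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


def two_state_scheme(
    k_fold: float,
    k_unfold: float,
    e_open: float = 0.3,
    e_closed: float = 0.8,
    e_sd: float = 0.07,
) -> KineticScheme:
    """Open/closed hairpin scheme.

    ``k_fold`` is the open->closed (folding) rate and ``k_unfold`` the
    closed->open (unfolding) rate, both in s^-1.  Defaults put the open
    (unfolded) state at low FRET (E ~ 0.3, large dye separation) and the
    closed (folded) state at high FRET (E ~ 0.8).
    """
    return KineticScheme(
        states=(
            StateSpec("open", e_open, e_sd),
            StateSpec("closed", e_closed, e_sd),
        ),
        rates=np.array([[0.0, k_fold], [k_unfold, 0.0]]),
    )


def three_state_scheme(
    k1: float,
    k2: float,
    k3: float,
    e_means: tuple[float, float, float] = (0.17, 0.38, 0.65),
    e_sd: float = 0.07,
    branching: tuple[float, float, float] = (0.8, 0.8, 0.5),
) -> KineticScheme:
    """Open / partially-folded / closed scheme with prescribed exit rates.

    ``k1``/``k2``/``k3`` are the total exit rates (s^-1) of the fully open,
    partial and fully closed states; ``branching`` gives the fraction of each
    state's exits that lands on the fully closed (respectively, for state 3,
    the fully open) state.  The default routes most open- and partial-state
    exits to the closed state with occasional open<->partial transitions, the
    transition pattern seen in three-state hairpin dynamics; closed-state
    exits split evenly.
    """
    b1, b2, b3 = branching
    rates = np.array(
        [
            [0.0, (1.0 - b1) * k1, b1 * k1],
            [(1.0 - b2) * k2, 0.0, b2 * k2],
            [b3 * k3, (1.0 - b3) * k3, 0.0],
        ]
    )
    return KineticScheme(
        states=(
            StateSpec("state1", e_means[0], e_sd),
            StateSpec("state2", e_means[1], e_sd),
            StateSpec("state3", e_means[2], e_sd),
        ),
        rates=rates,
    )


@dataclass(frozen=True)
class Trajectory:
    """A realized state path: contiguous segments covering [0, duration]."""

    states: np.ndarray  # int state index per segment
    starts: np.ndarray  # s
    ends: np.ndarray  # s
    duration: float

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int64)
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if not (len(states) == len(starts) == len(ends)):
            raise ValueError("segment arrays must have equal length")
        if len(states) == 0:
            raise ValueError("trajectory must contain at least one segment")
        if starts[0] != 0.0 or not np.isclose(ends[-1], self.duration):
            raise ValueError("segments must cover [0, duration]")
        if not np.allclose(starts[1:], ends[:-1]):
            raise ValueError("segments must be contiguous")
        if np.any(states[1:] == states[:-1]):
            raise ValueError("consecutive segments must differ in state")

    @property
    def n_segments(self) -> int:
        return len(self.states)

    def dwell_times(self) -> np.ndarray:
        return self.ends - self.starts

    def occupancy_fractions(self, n_states: int) -> np.ndarray:
        """Total time fraction spent in each state."""
        occ = np.zeros(n_states)
        np.add.at(occ, self.states, self.dwell_times())
        return occ / self.duration

    def bin_occupancy(self, bin_width: float, n_states: int) -> np.ndarray:
        """Per-bin occupancy fraction matrix, shape (n_bins, n_states).

        A trailing partial bin is dropped.
        """
        n_bins = int(np.floor(self.duration / bin_width + 1e-9))
        occ = np.zeros((n_bins, n_states))
        for s, t0, t1 in zip(self.states, self.starts, self.ends):
            b0 = int(t0 / bin_width)
            b1 = min(int(np.ceil(t1 / bin_width)), n_bins)
            if b0 >= n_bins:
                break
            edges = np.arange(b0, b1 + 1) * bin_width
            lo = np.maximum(edges[:-1], t0)
            hi = np.minimum(edges[1:], t1)
            occ[b0:b1, s] += np.clip(hi - lo, 0.0, None)
        return occ / bin_width


@dataclass(frozen=True)
class AcquisitionConfig:
    """Photon-detection model shared by the trace and burst simulators.

    Parameters
    ----------
    bin_width : s.  The analysis operates on 1 ms binned counts.
    brightness : expected detected photons per bin from one molecule.
    background_d, background_a : expected background photons per bin and
        channel (also used for the direct-acceptor channel).
    gamma : detection correction factor, the quantum-yield/detection-efficiency
        ratio of the acceptor over the donor channel; 0.88 for the Atto 550 /
        Atto 647N pair on SPAD detectors.
    contaminant_fractions : (donor-only, acceptor-only) burst fractions.
    """

    bin_width: float = 1.0e-3
    brightness: float = 100.0
    background_d: float = 0.5
    background_a: float = 0.5
    gamma: float = 0.88
    contaminant_fractions: tuple[float, float] = (0.05, 0.05)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")
        if self.background_d < 0 or self.background_a < 0:
            raise ValueError("backgrounds must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        fd, fa = self.contaminant_fractions
        if fd < 0 or fa < 0 or fd + fa >= 1.0:
            raise ValueError("contaminant fractions must be >= 0 and sum < 1")


@dataclass(frozen=True)
class ThermoGroundTruth:
    """Pressure dependence of the unfolding equilibrium.

    delta_v : cm^3 mol^-1, transition volume for closed->open (unfolding);
        negative when the open state has the smaller partial molar volume.
    keq_ref : equilibrium constant F_open/F_closed at p_ref.
    p_ref : bar.
    temperature : K.
    """

    delta_v: float
    keq_ref: float
    p_ref: float = 1.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.keq_ref <= 0:
            raise ValueError("keq_ref must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def keq(self, pressure_bar: float | np.ndarray) -> float | np.ndarray:
        """Keq(p) = keq_ref * exp(-dV (p - p_ref) / (R T))."""
        dp_pa = (np.asarray(pressure_bar, dtype=float) - self.p_ref) * BAR_TO_PA
        dv_m3 = self.delta_v * CM3_TO_M3
        out = self.keq_ref * np.exp(-dv_m3 * dp_pa / (R_GAS * self.temperature))
        return float(out) if np.isscalar(pressure_bar) else out
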