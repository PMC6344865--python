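"""Gaussian deconvolution of FRET-efficiency histograms into state fractions.

The E-histogram of a two-state hairpin shows a low-FRET (open, E ~ 0.3) and a
high-FRET (closed, E ~ 0.8) peak.  Peaks are fitted as Gaussians on the binned
normalized density by bounded nonlinear least squares with multiple restarts;
the fraction of each conformational state is the area of its peak(s) over the
total area, F_open = area(low-FRET) / total, F_closed = 1 - F_open.  An EM fit
on the raw E samples (:func:`fit_mixture_em`) is kept as an independent
statistical route to the same fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .bursts import EHistogram

logger = logging.getLogger(__name__)

SQRT2PI = np.sqrt(2.0 * np.pi)
DEFAULT_BOUNDARY = 0.45  # midpoint of the open (~0.3) and closed (~0.8) peaks
MIN_MEAN_SEPARATION = 0.02


@dataclass(frozen=True)
class GaussianComponent:
    weight: float  # area fraction in [0, 1]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("component sd must be > 0")


@dataclass(frozen=True)
class MixtureFit:
    """Sorted-by-mean Gaussian components; weights sum to 1."""

    components: tuple[GaussianComponent, ...]
    rss: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 4:
            raise ValueError("1 to 4 components supported")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"component weights sum to {total}, expected 1")

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])


@dataclass(frozen=True)
class StateFractions:
    f_open: float
    f_closed: float
    f_partial: float | None = None

    def __post_init__(self) -> None:
        total = self.f_open + self.f_closed + (self.f_partial or 0.0)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, expected 1")


def _model_density(x: np.ndarray, params: np.ndarray, k: int) -> np.ndarray:
    amps = params[:k]
    means = params[k : 2 * k]
    sds = params[2 * k :]
    out = np.zeros_like(x)
    for a, m, s in zip(amps, means, sds):
        out += a * np.exp(-0.5 * ((x - m) / s) ** 2)
    return out


def _components_from_params(params: np.ndarray, k: int) -> list[GaussianComponent]:
    amps = params[:k]
    means = params[k : 2 * k]
    sds = params[2 * k :]
    areas = amps * sds * SQRT2PI
    weights = areas / areas.sum()
    comps = [
        GaussianComponent(weight=float(w), mean=float(m), sd=float(s))
        for w, m, s in zip(weights, means, sds)
    ]
    comps.sort(key=lambda c: c.mean)
    return comps


def fit_mixture(
    hist: EHistogram,
    k: int,
    init_means: np.ndarray | None = None,
    restarts: int = 10,
    seed: int = 0,
) -> MixtureFit:
    """Fit k Gaussians to a normalized E-histogram by least squares.

    Amplitude/mean/width per component, bounded (means in [0,1], widths in
    [0.01, 0.5]); ``restarts`` jittered initializations (the first is
    unjittered, from ``init_means`` or density quantiles) and the lowest
    residual sum of squares wins.  Components are returned sorted by mean
    with area weights renormalized to sum 1.  Two components converging onto
    the same mean (within 0.02) trigger a logged refit at k-1.
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    x = hist.centers
    y = hist.density
    if int((y > 0).sum()) < 3 * k:
        raise ValueError(f"need at least {3 * k} nonzero bins for k={k}")
    rng = np.random.default_rng(seed)

    if init_means is None:
        # Quantiles of the density place inits inside the populated region.
        cdf = np.cumsum(y) / y.sum()
        qs = (np.arange(k) + 0.5) / k
        init_means = np.array([x[np.searchsorted(cdf, q)] for q in qs])
    init_means = np.asarray(init_means, dtype=float)
    if init_means.shape != (k,):
        raise ValueError("init_means must have length k")
    amp0 = max(y.max(), 1e-3)
    sd0 = 0.08

    lower = np.concatenate([np.zeros(k), np.zeros(k), np.full(k, 0.01)])
    upper = np.concatenate(
        [np.full(k, 50.0 * amp0 + 1.0), np.ones(k), np.full(k, 0.5)]
    )

    best = None
    for i in range(max(restarts, 1)):
        means0 = init_means if i == 0 else np.clip(
            init_means + rng.normal(0.0, 0.05, size=k), 0.01, 0.99
        )
        p0 = np.concatenate(
            [np.full(k, amp0 / max(k, 1)), means0, np.full(k, sd0)]
        )
        try:
            res = least_squares(
                lambda p: _model_density(x, p, k) - y,
                p0,
                bounds=(lower, upper),
                method="trf",
                max_nfev=2000,
            )
        except Exception:  # numerically failed restart
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise RuntimeError(
            f"mixture fit failed to converge in {restarts} restarts (k={k})"
        )
    rss, params = best
    comps = _components_from_params(params, k)
    means = np.array([c.mean for c in comps])
    if k > 1 and np.any(np.diff(means) < MIN_MEAN_SEPARATION):
        logger.info(
            "components collapsed (means %s); refitting with k=%d", means, k - 1
        )
        return fit_mixture(hist, k - 1, restarts=restarts, seed=seed)
    return MixtureFit(components=tuple(comps), rss=rss)


def fit_mixture_em(
    samples: np.ndarray, k: int, seed: int = 0
) -> MixtureFit:
    """EM (GaussianMixture) fit on raw E samples — the cross-check route."""
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=k, covariance_type="diag", n_init=5, random_state=seed
    )
    gm.fit(np.asarray(samples, dtype=float).reshape(-1, 1))
    comps = [
        GaussianComponent(
            weight=float(w), mean=float(m[0]), sd=float(np.sqrt(v[0]))
        )
        for w, m, v in zip(gm.weights_, gm.means_, gm.covariances_)
    ]
    comps.sort(key=lambda c: c.mean)
    w = np.array([c.weight for c in comps])
    comps = [
        GaussianComponent(weight=float(wi / w.sum()), mean=c.mean, sd=c.sd)
        for wi, c in zip(w, comps)
    ]
    return MixtureFit(components=tuple(comps), rss=float("nan"))


def assign_and_fractions(
    fit: MixtureFit,
    boundary: float = DEFAULT_BOUNDARY,
    overrides: dict[int, str] | None = None,
) -> StateFractions:
    """Map mixture components to conformational states and sum their areas.

    Default rule: component mean < ``boundary`` -> open, else closed.
    ``overrides`` maps component index (in mean-sorted order) to a label in
    {"open", "partial", "closed"} — needed when one conformational state
    carries a bimodal FRET distribution (e.g. under crowding, where the
    folded state shows peaks at E = 0.60 and 0.85 and the unfolded state at
    0.13 and 0.31).
    """
    if not 0.0 < boundary < 1.0:
        raise ValueError("boundary must lie in (0, 1)")
    overrides = overrides or {}
    f = {"open": 0.0, "partial": 0.0, "closed": 0.0}
    for i, comp in enumerate(fit.components):
        label = overrides.get(i)
        if label is None:
            label = "open" if comp.mean < boundary else "closed"
        if label not in f:
            raise ValueError(f"unknown state label {label!r}")
        f[label] += comp.weight
    if f["open"] == 0.0 or f["closed"] == 0.0:
        warnings.warn(
            "all components assigned to one state; fractions are degenerate",
            stacklevel=2,
        )
    total = sum(f.values())
    return StateFractions(
        f_open=f["open"] / total,
        f_closed=f["closed"] / total,
        f_partial=(f["partial"] / total) if f["partial"] > 0 else None,
    )
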