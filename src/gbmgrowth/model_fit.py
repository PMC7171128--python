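"""Parameter fits: Gompertz rate, noise strength, and waiting-time surfaces.

Three fitting stages parameterise the growth model and its survival
predictions:

1. ``fit_gompertz_rate`` — the deterministic intrinsic growth rate
   ``alpha(V) = a log(b/V)`` is linear in ``log V``, so (a, b) come from an
   ordinary least-squares regression of SGR on ``log V1``.
2. ``fit_noise_strength`` — the white-noise amplitude
   ``sigma(V) = c / (h + sqrt(V))`` is fitted to binned (volume, SD) pairs by
   bounded nonlinear least squares.
3. ``fit_mean_surface`` / ``fit_sd_surface`` — the Monte-Carlo waiting-time
   summaries over a (v0, vc) grid are condensed into closed-form surfaces:
   a plane ``mu(v0, vc) = beta0 + beta_v0 v0 + beta_vc vc`` for the mean and
   a restricted quadratic
   ``sigma(v0, vc) = gamma0 + gamma_v0 v0 + gamma_vc vc + gamma_v0vc v0 vc
   + gamma_vc2 vc^2`` (no ``v0^2`` term) for the SD, both by unweighted OLS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "MeanSurface",
    "SDSurface",
    "FPTTriple",
    "GompertzRateFit",
    "NoiseStrengthFit",
    "fit_gompertz_rate",
    "fit_noise_strength",
    "fit_mean_surface",
    "fit_sd_surface",
]


@dataclass(frozen=True)
class MeanSurface:
    """Plane for the mean waiting time: ``beta0 + beta_v0 * v0 + beta_vc * vc`` (days)."""

    beta0: float
    beta_v0: float
    beta_vc: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in (self.beta0, self.beta_v0, self.beta_vc)):
            raise ValueError("surface coefficients must be finite")

    def evaluate(self, v0: float, vc: float) -> float:
        return self.beta0 + self.beta_v0 * v0 + self.beta_vc * vc

    def to_dict(self) -> dict[str, float]:
        return {"beta0": self.beta0, "beta_v0": self.beta_v0, "beta_vc": self.beta_vc}

    @classmethod
    def from_dict(cls, d: dict) -> "MeanSurface":
        return cls(float(d["beta0"]), float(d["beta_v0"]), float(d["beta_vc"]))


@dataclass(frozen=True)
class SDSurface:
    """Restricted quadratic for the waiting-time SD (days).

    ``gamma0 + gamma_v0 v0 + gamma_vc vc + gamma_v0vc v0*vc + gamma_vc2 vc^2``
    — deliberately without a ``v0^2`` term.
    """

    gamma0: float
    gamma_v0: float
    gamma_vc: float
    gamma_v0vc: float
    gamma_vc2: float

    def __post_init__(self) -> None:
        vals = (self.gamma0, self.gamma_v0, self.gamma_vc, self.gamma_v0vc, self.gamma_vc2)
        if not all(math.isfinite(x) for x in vals):
            raise ValueError("surface coefficients must be finite")

    def evaluate(self, v0: float, vc: float) -> float:
        return (
            self.gamma0
            + self.gamma_v0 * v0
            + self.gamma_vc * vc
            + self.gamma_v0vc * v0 * vc
            + self.gamma_vc2 * vc * vc
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "gamma0": self.gamma0,
            "gamma_v0": self.gamma_v0,
            "gamma_vc": self.gamma_vc,
            "gamma_v0vc": self.gamma_v0vc,
            "gamma_vc2": self.gamma_vc2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SDSurface":
        return cls(
            float(d["gamma0"]),
            float(d["gamma_v0"]),
            float(d["gamma_vc"]),
            float(d["gamma_v0vc"]),
            float(d["gamma_vc2"]),
        )


@dataclass(frozen=True)
class FPTTriple:
    """A grid cell of the waiting-time study: (v0, vc, mean, SD), days.

    ``sigma`` may be exactly 0 in the deterministic (c = 0) limit.
    """

    v0: float
    vc: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.vc <= self.v0:
            raise ValueError("vc must exceed v0")
        if self.mu <= 0 or self.sigma < 0:
            raise ValueError("mu must be positive and sigma non-negative")


@dataclass(frozen=True)
class GompertzRateFit:
    """OLS estimate of the Gompertz rate law with basic diagnostics."""

    a: float
    b: float
    slope: float
    intercept: float
    slope_stderr: float
    r_squared: float


@dataclass(frozen=True)
class NoiseStrengthFit:
    """Nonlinear least-squares estimate of sigma(V) = c / (h + sqrt(V))."""

    c: float
    h: float
    cost: float
    identifiable: bool = True


def fit_gompertz_rate(points: Sequence) -> GompertzRateFit:
    """Estimate (a, b) of ``alpha(V) = a log(b/V)`` from SGR points.

    ``SGR = a log b - a log V``, so OLS of SGR on ``log V`` gives slope
    ``-a`` and intercept ``a log b``.  The slope must come out negative
    (growth rate decreasing in volume) for the Gompertz law to apply.
    """
    if len(points) < 2:
        raise ValueError("need at least two SGR points")
    v = np.array([p.v for p in points], dtype=float)
    sgr = np.array([p.sgr for p in points], dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("degenerate design: all volumes equal")
    X = sm.add_constant(np.log(v))
    res = sm.OLS(sgr, X).fit()
    intercept, slope = res.params
    if slope >= 0:
        raise ValueError(
            "fitted slope of SGR on log V is non-negative; the Gompertz rate "
            "a would not be positive"
        )
    a = -float(slope)
    b = float(math.exp(intercept / a))
    return GompertzRateFit(
        a=a,
        b=b,
        slope=float(slope),
        intercept=float(intercept),
        slope_stderr=float(res.bse[1]),
        r_squared=float(res.rsquared),
    )


def fit_noise_strength(
    pairs: Sequence[tuple[float, float]],
    init: tuple[float, float] = (0.1, 0.5),
    n_restarts: int = 5,
) -> NoiseStrengthFit:
    """Fit ``sigma(V) = c / (h + sqrt(V))`` to (volume, SD) pairs.

    Bounded least squares keeps ``c >= 0`` and ``h > 0``; on solver failure
    the fit restarts from perturbed initial values before giving up.  When
    the SDs carry no variation the ratio ``c / (h + sqrt(V))`` cannot be
    resolved — the returned fit is flagged non-identifiable.
    """
    v = np.array([p[0] for p in pairs], dtype=float)
    s = np.array([p[1] for p in pairs], dtype=float)
    if v.size < 2:
        raise ValueError("need at least two (volume, SD) pairs")
    if np.any(v <= 0) or np.any(s <= 0):
        raise ValueError("volumes and SDs must be positive")

    identifiable = True
    if np.ptp(s) < 1e-12 * max(1.0, float(np.max(s))):
        identifiable = False
        warnings.warn(
            "all dispersion values are equal: (c, h) are not jointly "
            "identifiable (only a degenerate ridge is constrained)",
            stacklevel=2,
        )

    def resid(theta):
        c, h = theta
        return c / (h + np.sqrt(v)) - s

    rng = np.random.default_rng(0)
    x0 = np.array(init, dtype=float)
    last_exc: Exception | None = None
    for attempt in range(n_restarts + 1):
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=([0.0, 1e-8], [np.inf, np.inf]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            if sol.success and np.all(np.isfinite(sol.x)):
                c, h = sol.x
                return NoiseStrengthFit(
                    c=float(c), h=float(h), cost=float(sol.cost), identifiable=identifiable
                )
        except Exception as exc:  # pragma: no cover - solver pathologies
            last_exc = exc
        x0 = np.abs(np.array(init) * (1.0 + 0.5 * rng.standard_normal(2))) + 1e-3
    raise RuntimeError(
        f"noise-strength fit failed after {n_restarts + 1} starts"
        + (f": {last_exc}" if last_exc else "")
    )


def _ols_exact(design: np.ndarray, y: np.ndarray, what: str) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError(f"rank-deficient design for the {what} fit")
    return coef


def fit_mean_surface(triples: Sequence[FPTTriple]) -> MeanSurface:
    """OLS plane {1, v0, vc} through the grid means."""
    if len(triples) < 3:
        raise ValueError("need at least three triples")
    v0 = np.array([t.v0 for t in triples])
    vc = np.array([t.vc for t in triples])
    mu = np.array([t.mu for t in triples])
    X = np.column_stack([np.ones_like(v0), v0, vc])
    beta = _ols_exact(X, mu, "mean surface")
    return MeanSurface(beta0=float(beta[0]), beta_v0=float(beta[1]), beta_vc=float(beta[2]))


def fit_sd_surface(triples: Sequence[FPTTriple]) -> SDSurface:
    """OLS fit with regressors {1, v0, vc, v0*vc, vc^2} through the grid SDs."""
    if len(triples) < 5:
        raise ValueError("need at least five triples")
    v0 = np.array([t.v0 for t in triples])
    vc = np.array([t.vc for t in triples])
    sd = np.array([t.sigma for t in triples])
    X = np.column_stack([np.ones_like(v0), v0, vc, v0 * vc, vc * vc])
    g = _ols_exact(X, sd, "SD surface")
    return SDSurface(
        gamma0=float(g[0]),
        gamma_v0=float(g[1]),
        gamma_vc=float(g[2]),
        gamma_v0vc=float(g[3]),
        gamma_vc2=float(g[4]),
    )
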