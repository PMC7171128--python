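"""Survival-time calculus: waiting-time surfaces and resection protocols.

Survival is modelled as the first-passage time of the stochastic Gompertz
volume process to a death volume ``vT``.  Monte-Carlo sampling over a grid of
(starting volume, stopping volume) pairs shows the waiting time
``T_{v0,vc}`` to be approximately normal, so each pair is condensed to a
``Normal(mu(v0, vc), sigma(v0, vc))`` via the fitted surfaces of
:mod:`gbmgrowth.model_fit`.

Resection protocols chain waiting-time segments: the tumor grows from its
diagnosed volume to a trigger volume, a fraction of it is removed, and growth
resumes from the post-resection volume.  Total survival is the sum of the
segments' jointly normal waiting times — its mean is the sum of the segment
means (independent of any correlation), and its SD is
``sqrt(sigma^T R sigma)`` for segment-SD vector ``sigma`` and correlation
matrix ``R``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gompertz_sde import (
    FPTSample,
    NormalSummary,
    SDEParams,
    sample_first_passage_multi,
)
from .model_fit import FPTTriple, MeanSurface, SDSurface

__all__ = [
    "SurvivalSurfaces",
    "ResectionPlan",
    "fpt_normal_summary",
    "eval_mean_surface",
    "eval_sd_surface",
    "untreated_survival",
    "immediate_resection_survival",
    "staged_survival",
    "build_fpt_grid",
    "grid_to_frame",
]

# Box covered by the default waiting-time grid; evaluations outside it are
# extrapolations and are flagged with a warning.
_FITTED_V0 = (10.0, 60.0)
_FITTED_VC = (20.0, 100.0)


@dataclass(frozen=True)
class SurvivalSurfaces:
    """A fitted (mean, SD) surface pair for the waiting-time distribution."""

    mean: MeanSurface
    sd: SDSurface

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "sd": self.sd.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalSurfaces":
        return cls(mean=MeanSurface.from_dict(d["mean"]), sd=SDSurface.from_dict(d["sd"]))


@dataclass
class ResectionPlan:
    """A staged surgical-resection protocol.

    ``stages`` is an ordered list of ``(trigger_volume, cut_fraction)``: the
    tumor is allowed to grow to each trigger, where the given fraction of its
    volume is removed.  ``corr`` is the correlation matrix across the K+1
    waiting-time segments (identity when omitted); the correlation values are
    scenario parameters, not estimates.
    """

    v0: float
    stages: Sequence[tuple[float, float]] = field(default_factory=tuple)
    vT: float = 100.0
    corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stages = tuple((float(t), float(c)) for t, c in self.stages)
        if self.v0 <= 0:
            raise ValueError("diagnosed volume v0 must be positive")
        current = self.v0
        for k, (trigger, cut) in enumerate(self.stages):
            if not (0 <= cut < 1):
                raise ValueError(f"stage {k}: cut fraction must lie in [0, 1)")
            if trigger < current:
                raise ValueError(
                    f"stage {k}: trigger {trigger} is below the volume {current} "
                    "entering the segment"
                )
            current = trigger * (1.0 - cut)
        if self.vT <= current:
            raise ValueError("death volume vT must exceed the final post-resection volume")
        n_seg = len(self.segments())
        if self.corr is not None:
            R = np.asarray(self.corr, dtype=float)
            if R.shape != (n_seg, n_seg):
                raise ValueError(f"corr must be {n_seg}x{n_seg}")
            if not np.allclose(R, R.T, atol=1e-12):
                raise ValueError("corr must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-12):
                raise ValueError("corr must have a unit diagonal")
            if np.min(np.linalg.eigvalsh(R)) < -1e-10:
                raise ValueError("corr must be positive semidefinite")
            self.corr = R

    def segments(self) -> list[tuple[float, float]]:
        """(start volume, end volume) of each growth segment, ending at vT.

        Zero-length segments (a resection triggered at the volume entering
        the segment, i.e. an immediate cut) have waiting time identically 0
        and are skipped.
        """
        segs = []
        current = self.v0
        for trigger, cut in self.stages:
            if trigger > current:
                segs.append((current, trigger))
            current = trigger * (1.0 - cut)
        segs.append((current, self.vT))
        return segs

    def correlation(self) -> np.ndarray:
        if self.corr is None:
            return np.eye(len(self.segments()))
        return self.corr


def fpt_normal_summary(sample: FPTSample) -> NormalSummary:
    """Sample mean and SD (n-1) of the first-passage draws."""
    if sample.n_censored > 0:
        warnings.warn(
            f"{sample.n_censored} censored paths excluded from the waiting-time "
            "summary",
            stacklevel=2,
        )
    if sample.n < 2:
        raise ValueError("need at least two uncensored draws")
    return NormalSummary(
        mu=float(np.mean(sample.times)), sigma=float(np.std(sample.times, ddof=1))
    )


def _warn_extrapolation(v0: float, vc: float) -> None:
    if not (_FITTED_V0[0] <= v0 <= _FITTED_V0[1] and _FITTED_VC[0] <= vc <= _FITTED_VC[1]):
        warnings.warn(
            f"surface evaluated outside the fitted grid at (v0={v0}, vc={vc}); "
            "extrapolated value",
            stacklevel=3,
        )


def eval_mean_surface(surface: MeanSurface, v0: float, vc: float) -> float:
    """Mean waiting time in days; extrapolations (possibly negative) are warned."""
    _warn_extrapolation(v0, vc)
    val = surface.evaluate(v0, vc)
    if val < 0:
        warnings.warn(
            f"negative mean waiting time {val:.3f} d at (v0={v0}, vc={vc}): "
            "extrapolation artefact, returned as-is",
            stacklevel=2,
        )
    return val


def eval_sd_surface(surface: SDSurface, v0: float, vc: float) -> float:
    """Waiting-time SD in days; a non-positive value is an error."""
    _warn_extrapolation(v0, vc)
    val = surface.evaluate(v0, vc)
    if val <= 0:
        raise ValueError(f"non-positive waiting-time SD at (v0={v0}, vc={vc})")
    return val


def untreated_survival(v0: float, vT: float, surfaces: SurvivalSurfaces) -> NormalSummary:
    """Survival distribution for untreated growth from ``v0`` to death at ``vT``."""
    if not (0 < v0 < vT):
        raise ValueError("require 0 < v0 < vT")
    return NormalSummary(
        mu=eval_mean_surface(surfaces.mean, v0, vT),
        sigma=eval_sd_surface(surfaces.sd, v0, vT),
    )


def immediate_resection_survival(
    v0: float, cut_fraction: float, vT: float, surfaces: SurvivalSurfaces
) -> NormalSummary:
    """Survival after removing ``cut_fraction`` of the tumor at diagnosis."""
    if not (0 <= cut_fraction < 1):
        raise ValueError("cut_fraction must lie in [0, 1)")
    v_post = v0 * (1.0 - cut_fraction)
    return untreated_survival(v_post, vT, surfaces)


def staged_survival(plan: ResectionPlan, surfaces: SurvivalSurfaces) -> NormalSummary:
    """Total survival for a staged protocol as a correlated normal sum.

    Mean = sum of segment means (warnings aside, negative extrapolated
    segment means are kept).  SD = ``sqrt(sigma^T R sigma)``.
    """
    mus = []
    sds = []
    for start, end in plan.segments():
        mus.append(eval_mean_surface(surfaces.mean, start, end))
        sds.append(eval_sd_surface(surfaces.sd, start, end))
    sd_vec = np.array(sds)
    R = plan.correlation()
    var = float(sd_vec @ R @ sd_vec)
    if var < 0:
        raise ValueError("correlation matrix produced a negative total variance")
    return NormalSummary(mu=float(np.sum(mus)), sigma=math.sqrt(var))


def build_fpt_grid(
    params: SDEParams,
    v0_list: Sequence[float] = (10, 20, 30, 40, 50, 60),
    vc_list: Sequence[float] = (20, 30, 40, 50, 60, 70, 80, 90, 100),
    n_paths: int = 500,
    step: float = 0.05,
    seed: int | None = None,
    min_gap: float = 10.0,
) -> list[FPTTriple]:
    """Monte-Carlo waiting-time summaries over a (v0, vc) grid.

    Cells with ``vc < v0 + min_gap`` are skipped (the defaults yield the
    39-cell study grid).  All thresholds sharing a starting volume are
    monitored on the same simulated paths, and each starting volume gets an
    independent child seed so the grid is reproducible regardless of order.
    """
    if not len(v0_list) or not len(vc_list):
        raise ValueError("v0_list and vc_list must be non-empty")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(v0_list)) % (2**31)
    triples: list[FPTTriple] = []
    for v0, child in zip(v0_list, child_seeds):
        thresholds = [vc for vc in vc_list if vc >= v0 + min_gap]
        if not thresholds:
            continue
        samples = sample_first_passage_multi(
            float(v0), thresholds, params, n_paths=n_paths, step=step,
            seed=int(child),
        )
        for s in samples:
            summ = fpt_normal_summary(s)
            triples.append(FPTTriple(v0=float(v0), vc=s.vc, mu=summ.mu, sigma=summ.sigma))
    return triples


def grid_to_frame(
    triples: Sequence[FPTTriple], n_paths: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Tabulate a waiting-time grid as v0_ml, vc_ml, mean_days, sd_days (+ provenance)."""
    df = pd.DataFrame(
        [(t.v0, t.vc, t.mu, t.sigma) for t in triples],
        columns=["v0_ml", "vc_ml", "mean_days", "sd_days"],
    )
    if n_paths is not None:
        df["n_paths"] = n_paths
    if seed is not None:
        df["seed"] = seed
    return df
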