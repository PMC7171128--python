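"""Synthetic paired-scan cohorts with the structure of the Trondheim data.

The real cohort (94 untreated glioblastoma patients, two pre-surgery MRI
volumes each) is not publicly deposited, so every pipeline stage is exercised
on cohorts generated from the model itself: first-scan volumes are drawn from
a log-normal with most mass between 1 and 70 mL and an upper tail reaching
~146 mL, inter-scan intervals are uniform over days-to-weeks, and the second
volume is produced by simulating the fitted SDE forward over the interval.
Records are kept only if the tumor grew between scans (the same selection the
original cohort applied), which mildly biases fitted growth rates upward —
see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gompertz_sde import SDEParams, SimulationError, simulate_terminal
from .growth_stats import PatientRecord
from .model_fit import FPTTriple, MeanSurface, SDSurface
from .reference import TRONDHEIM_PARAMS

__all__ = ["CohortConfig", "generate_cohort", "generate_surface_triples", "default_grid_design"]


@dataclass(frozen=True)
class CohortConfig:
    """Sampling configuration for a synthetic paired-scan cohort.

    Defaults emulate the Trondheim cohort's structure: n = 94 patients,
    log-normal first-scan volumes (meanlog = ln 8 mL, sdlog = 1.05, putting
    ~95% of draws between 1 and 65 mL), inter-scan intervals uniform on
    7-49 days, and growth between scans enforced by redrawing.
    """

    n_patients: int = 94
    v1_log_mean: float = math.log(8.0)
    v1_log_sd: float = 1.05
    dt_min: float = 7.0
    dt_max: float = 49.0
    true_params: SDEParams = TRONDHEIM_PARAMS
    require_growth: bool = True
    max_path_retries: int = 25
    max_patient_redraws: int = 10
    step: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.v1_log_sd <= 0:
            raise ValueError("v1_log_sd must be positive")
        if not (0 < self.dt_min <= self.dt_max):
            raise ValueError("require 0 < dt_min <= dt_max")
        if self.step <= 0:
            raise ValueError("step must be positive")


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a cohort of (v1, dt, v2) records from the configured SDE.

    Each patient: draw v1 and dt, simulate one volume path over dt to get v2.
    With ``require_growth`` the path is redrawn until v2 > v1 (up to
    ``max_path_retries``); if a patient's draw cannot produce growth the
    patient's (v1, dt) is redrawn entirely, and a patient whose redraw budget
    is also exhausted raises :class:`SimulationError` naming the index.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        record = None
        for _redraw in range(config.max_patient_redraws):
            v1 = float(rng.lognormal(config.v1_log_mean, config.v1_log_sd))
            dt = float(rng.uniform(config.dt_min, config.dt_max))
            for _retry in range(config.max_path_retries):
                v2 = float(
                    simulate_terminal(
                        v1, dt, config.true_params, n_paths=1, step=config.step, rng=rng
                    )[0]
                )
                if not config.require_growth or v2 > v1:
                    record = PatientRecord(
                        patient_id=f"SYN-{i + 1:04d}", v1=v1, dt=dt, v2=v2
                    )
                    break
            if record is not None:
                break
        if record is None:
            raise SimulationError(
                f"patient {i}: retry budget exhausted without observing growth"
            )
        records.append(record)
    return records


def default_grid_design() -> list[tuple[float, float]]:
    """The 39-point (v0, vc) design of the waiting-time study."""
    return [
        (float(v0), float(vc))
        for v0 in (10, 20, 30, 40, 50, 60)
        for vc in (20, 30, 40, 50, 60, 70, 80, 90, 100)
        if vc >= v0 + 10
    ]


def generate_surface_triples(
    mean_surface: MeanSurface,
    sd_surface: SDSurface,
    design: list[tuple[float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    max_redraws: int = 100,
) -> list[FPTTriple]:
    """Waiting-time triples drawn from given surfaces, for fit testing.

    With ``noise_sd = 0`` the triples lie exactly on the surfaces, so
    refitting recovers the coefficients to numerical precision.  Gaussian
    perturbations with non-positive resulting SDs are redrawn (bounded).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if design is None:
        design = default_grid_design()
    rng = np.random.default_rng(seed)
    triples: list[FPTTriple] = []
    for v0, vc in design:
        mu = mean_surface.evaluate(v0, vc)
        sigma = sd_surface.evaluate(v0, vc)
        if noise_sd > 0:
            mu = mu + float(rng.normal(0.0, noise_sd))
            for _ in range(max_redraws):
                cand = sigma + float(rng.normal(0.0, noise_sd))
                if cand > 0:
                    sigma = cand
                    break
            else:
                raise RuntimeError(
                    f"could not draw a positive SD at (v0={v0}, vc={vc})"
                )
        triples.append(FPTTriple(v0=v0, vc=vc, mu=mu, sigma=sigma))
    return triples
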