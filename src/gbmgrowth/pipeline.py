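"""Pipeline orchestration: cohort verification and the full analysis run.

``verify_cohort`` implements the paired-scan check used to validate the
model: for each record the SDE is simulated forward from the first-scan
volume over the inter-scan interval, and the observed second volume is tested
against the ensemble's ``mean +/- k * SD`` band (k = 3 by default, roughly a
99% band).  ``run_full_analysis`` chains every stage — cohort generation or
loading, parameter fitting, verification, the waiting-time grid, surface
fitting and the protocol tables — writing each artifact with its seed and a
hash of the effective configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gompertz_sde import SDEParams, simulate_terminal
from .growth_stats import (
    PatientRecord,
    bin_by_volume,
    bin_dispersion,
    cohort_sgr,
    read_cohort_csv,
    write_cohort_csv,
)
from .model_fit import (
    fit_gompertz_rate,
    fit_mean_surface,
    fit_noise_strength,
    fit_sd_surface,
)
from .reference import DEATH_VOLUME_ML
from .survival_calc import (
    ResectionPlan,
    SurvivalSurfaces,
    build_fpt_grid,
    grid_to_frame,
    immediate_resection_survival,
    staged_survival,
    untreated_survival,
)
from .synthetic_cohort import CohortConfig, generate_cohort

__all__ = [
    "VerificationRow",
    "VerificationReport",
    "AnalysisConfig",
    "verify_cohort",
    "run_full_analysis",
]

logger = logging.getLogger("gbmgrowth")

DEFAULT_BIN_EDGES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@dataclass(frozen=True)
class VerificationRow:
    patient_id: str
    mu: float
    sigma: float
    v2: float
    hit: bool


@dataclass
class VerificationReport:
    """Per-record prediction-band hits plus aggregate percentages."""

    rows: list[VerificationRow]
    k_sd: float
    subset_threshold_ml: float

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def n_hit(self) -> int:
        return sum(r.hit for r in self.rows)

    @property
    def percent_hit(self) -> float:
        return 100.0 * self.n_hit / self.n_total

    def _subset(self) -> list[VerificationRow]:
        return [r for r in self.rows if r.v2 < self.subset_threshold_ml]

    @property
    def n_subset(self) -> int:
        return len(self._subset())

    @property
    def n_subset_hit(self) -> int:
        return sum(r.hit for r in self._subset())

    @property
    def percent_subset_hit(self) -> float:
        n = self.n_subset
        return 100.0 * self.n_subset_hit / n if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.patient_id, r.mu, r.sigma, r.v2, r.hit) for r in self.rows],
            columns=["patient_id", "pred_mu_ml", "pred_sigma_ml", "observed_v2_ml", "hit"],
        )

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_hit": self.n_hit,
            "percent_hit": self.percent_hit,
            "subset_threshold_ml": self.subset_threshold_ml,
            "n_subset": self.n_subset,
            "n_subset_hit": self.n_subset_hit,
            "percent_subset_hit": self.percent_subset_hit,
            "k_sd": self.k_sd,
        }


def verify_cohort(
    records: Sequence[PatientRecord],
    params: SDEParams,
    n_paths: int = 500,
    k_sd: float = 3.0,
    subset_threshold_ml: float = 50.0,
    seed: int | None = None,
    step: float = 0.05,
) -> VerificationReport:
    """Test each record's observed V2 against the simulated prediction band.

    A record is a *hit* when ``|V2 - mu| <= k_sd * sigma`` for the ensemble
    mean and SD at the record's inter-scan time.  The report aggregates hit
    percentages overall and for records with ``V2 < subset_threshold_ml``
    (small tumors are predicted markedly better).
    """
    if not records:
        raise ValueError("cohort is empty")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(records)) % (2**31)
    rows = []
    for record, child in zip(records, child_seeds):
        rng = np.random.default_rng(int(child))
        terminal = simulate_terminal(
            record.v1, record.dt, params, n_paths=n_paths, step=step, rng=rng
        )
        mu = float(np.mean(terminal))
        sigma = float(np.std(terminal, ddof=1))
        hit = abs(record.v2 - mu) <= k_sd * sigma
        rows.append(
            VerificationRow(
                patient_id=record.patient_id, mu=mu, sigma=sigma, v2=record.v2, hit=bool(hit)
            )
        )
    return VerificationReport(rows=rows, k_sd=k_sd, subset_threshold_ml=subset_threshold_ml)


@dataclass
class AnalysisConfig:
    """Effective configuration of a full analysis run.

    ``cohort_csv = None`` requests a synthetic cohort.  All randomness flows
    from ``seed``, expanded into independent per-stage child seeds.
    """

    seed: int = 0
    cohort_csv: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    dispersion_statistic: str = "sgr"
    verify_n_paths: int = 500
    verify_k_sd: float = 3.0
    verify_subset_threshold_ml: float = 50.0
    grid_v0: tuple[float, ...] = (10, 20, 30, 40, 50, 60)
    grid_vc: tuple[float, ...] = (20, 30, 40, 50, 60, 70, 80, 90, 100)
    grid_n_paths: int = 500
    step: float = 0.05
    death_volume_ml: float = DEATH_VOLUME_ML
    survival_v0: tuple[float, ...] = (1, 2, 5, 10, 20, 30, 50)
    resection_fractions: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 0.98)
    staged_v0: float = 1.0
    staged_triggers: tuple[float, ...] = (2, 5, 10, 20, 30, 50)
    staged_rhos: tuple[float, ...] = (0.0, 0.5, 0.8)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["true_params"] = self.cohort.true_params.to_dict()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_full_analysis(config: AnalysisConfig, out_dir) -> dict:
    """Run every stage and write all artifacts under ``out_dir``.

    Returns a bundle dict with the fitted parameters, surfaces, verification
    summary and the paths of every artifact.  Deterministic given
    ``config.seed``; any stage failure propagates after earlier artifacts
    were already written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    seeds = _stage_seeds(config.seed, 4)
    run_log = out / "run_log.jsonl"

    def log_stage(stage: str, **info):
        entry = {"stage": stage, "config_hash": cfg_hash, **info}
        with run_log.open("a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
        logger.info("stage %s done: %s", stage, info)

    if run_log.exists():
        run_log.unlink()

    t0 = time.perf_counter()
    # --- stage 1: cohort ---
    if config.cohort_csv is not None:
        records = read_cohort_csv(config.cohort_csv)
        cohort_seed = None
    else:
        cohort_seed = seeds[0]
        records = generate_cohort(dataclasses.replace(config.cohort, seed=cohort_seed))
    cohort_path = out / "cohort.csv"
    write_cohort_csv(records, cohort_path)
    log_stage("cohort", n_records=len(records), seed=cohort_seed)

    # --- stage 2: parameter fits ---
    points = cohort_sgr(records)
    rate_fit = fit_gompertz_rate(points)
    bins = bin_by_volume(records, list(config.bin_edges))
    pairs = bin_dispersion(bins, statistic=config.dispersion_statistic)
    noise_fit = fit_noise_strength(pairs)
    fitted = SDEParams(a=rate_fit.a, b=rate_fit.b, c=noise_fit.c, h=noise_fit.h)
    params_path = out / "fitted_params.json"
    params_path.write_text(
        json.dumps(
            {
                **fitted.to_dict(),
                "r_squared": rate_fit.r_squared,
                "dispersion_statistic": config.dispersion_statistic,
                "seed": config.seed,
                "config_hash": cfg_hash,
            },
            indent=2,
            sort_keys=True,
        )
    )
    log_stage("fit_params", a=fitted.a, b=fitted.b, c=fitted.c, h=fitted.h)

    # --- stage 3: verification ---
    report = verify_cohort(
        records,
        fitted,
        n_paths=config.verify_n_paths,
        k_sd=config.verify_k_sd,
        subset_threshold_ml=config.verify_subset_threshold_ml,
        seed=seeds[1],
        step=config.step,
    )
    verification_path = out / "verification.csv"
    report.to_frame().to_csv(verification_path, index=False)
    (out / "verification_summary.json").write_text(
        json.dumps({**report.summary(), "seed": seeds[1], "config_hash": cfg_hash}, indent=2)
    )
    log_stage("verify", **report.summary())

    # --- stage 4: waiting-time grid ---
    triples = build_fpt_grid(
        fitted,
        v0_list=config.grid_v0,
        vc_list=config.grid_vc,
        n_paths=config.grid_n_paths,
        step=config.step,
        seed=seeds[2],
    )
    grid_path = out / "fpt_grid.csv"
    grid_to_frame(triples, n_paths=config.grid_n_paths, seed=seeds[2]).to_csv(
        grid_path, index=False
    )
    log_stage("fpt_grid", n_cells=len(triples), seed=seeds[2])

    # --- stage 5: surfaces ---
    surfaces = SurvivalSurfaces(mean=fit_mean_surface(triples), sd=fit_sd_surface(triples))
    surfaces_path = out / "surfaces.json"
    surfaces_path.write_text(
        json.dumps(
            {**surfaces.to_dict(), "seed": seeds[2], "config_hash": cfg_hash},
            indent=2,
            sort_keys=True,
        )
    )
    log_stage("fit_surfaces", **surfaces.mean.to_dict())

    # --- stage 6: protocol tables ---
    vT = config.death_volume_ml
    untreated_rows = []
    for v0 in config.survival_v0:
        s = untreated_survival(v0, vT, surfaces)
        untreated_rows.append((v0, s.mu, s.sigma))
    untreated_df = pd.DataFrame(untreated_rows, columns=["v0_ml", "mean_days", "sd_days"])
    resection_rows = []
    for v0 in config.survival_v0:
        for frac in config.resection_fractions:
            s = immediate_resection_survival(v0, frac, vT, surfaces)
            resection_rows.append((v0, frac, s.mu, s.sigma))
    resection_df = pd.DataFrame(
        resection_rows, columns=["v0_ml", "cut_fraction", "mean_days", "sd_days"]
    )
    staged_rows = []
    for trigger in config.staged_triggers:
        for frac in config.resection_fractions:
            for rho in config.staged_rhos:
                plan = ResectionPlan(
                    v0=config.staged_v0,
                    stages=[(trigger, frac)],
                    vT=vT,
                    corr=np.array([[1.0, rho], [rho, 1.0]]),
                )
                s = staged_survival(plan, surfaces)
                staged_rows.append((config.staged_v0, trigger, frac, rho, s.mu, s.sigma))
    staged_df = pd.DataFrame(
        staged_rows,
        columns=["v0_ml", "trigger_ml", "cut_fraction", "rho", "mean_days", "sd_days"],
    )
    untreated_path = out / "survival_untreated.csv"
    resection_path = out / "survival_immediate_resection.csv"
    staged_path = out / "survival_delayed_resection.csv"
    untreated_df.to_csv(untreated_path, index=False)
    resection_df.to_csv(resection_path, index=False)
    staged_df.to_csv(staged_path, index=False)
    log_stage(
        "protocol_tables",
        n_untreated=len(untreated_df),
        n_resection=len(resection_df),
        n_staged=len(staged_df),
    )

    manifest = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "stage_seeds": seeds,
        "elapsed_s": round(time.perf_counter() - t0, 3),
        "artifacts": {
            "cohort": cohort_path.name,
            "fitted_params": params_path.name,
            "verification": verification_path.name,
            "fpt_grid": grid_path.name,
            "surfaces": surfaces_path.name,
            "survival_untreated": untreated_path.name,
            "survival_immediate_resection": resection_path.name,
            "survival_delayed_resection": staged_path.name,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "records": records,
        "fitted_params": fitted,
        "verification": report,
        "triples": triples,
        "surfaces": surfaces,
        "artifacts": {k: out / v for k, v in manifest["artifacts"].items()},
        "config_hash": cfg_hash,
    }
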