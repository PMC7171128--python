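"""Published reference values for the glioblastoma growth model.

These constants are the printed outputs of the original analysis of the
Trondheim cohort (94 untreated glioblastoma patients with paired MRI scans):
the fitted SDE parameters, the 39-cell Monte-Carlo waiting-time grid, the
waiting-time surfaces condensed from that grid, and the three independently
collected Seattle paired-scan records used for re-verification.  They serve
as fixed inputs for reproducing the survival tables and as cross-checks for
this package's own fitting and simulation pipeline; nothing here is computed
at import time.
"""

from __future__ import annotations

from .gompertz_sde import SDEParams
from .growth_stats import PatientRecord
from .model_fit import FPTTriple, MeanSurface, SDSurface

__all__ = [
    "TRONDHEIM_PARAMS",
    "PUBLISHED_MEAN_SURFACE",
    "PUBLISHED_SD_SURFACE",
    "WAITING_TIME_GRID",
    "SEATTLE_RECORDS",
    "DEATH_VOLUME_ML",
    "DEFAULT_V0_GRID",
    "DEFAULT_VC_GRID",
]

TRONDHEIM_PARAMS = SDEParams(a=0.009916, b=121.6, c=0.0769, h=0.2241)
"""SDE constants fitted to the Trondheim cohort.

``a`` and ``b`` come from the SGR-on-log-volume regression, ``c`` and ``h``
from the binned-dispersion fit of sigma(V) = c / (h + sqrt(V)).
"""

DEATH_VOLUME_ML = 100.0
"""Tumor volume equated with patient death in the survival tables.

Below the fitted carrying capacity (121.6 mL) so that the threshold is
reached by drift, not by noise alone.
"""

PUBLISHED_MEAN_SURFACE = MeanSurface(beta0=-10.98, beta_v0=-2.643, beta_vc=2.803)
"""Mean waiting-time surface mu(v0, vc) fitted to :data:`WAITING_TIME_GRID`."""

PUBLISHED_SD_SURFACE = SDSurface(
    gamma0=15.28,
    gamma_v0=-0.1914,
    gamma_vc=-0.3376,
    gamma_v0vc=0.001166,
    gamma_vc2=0.004797,
)
"""SD waiting-time surface sigma(v0, vc) fitted to :data:`WAITING_TIME_GRID`."""

DEFAULT_V0_GRID = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
DEFAULT_VC_GRID = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)

# (v0, vc, mean_days, sd_days): 500-path Monte-Carlo waiting-time summaries
# for every combination with vc >= v0 + 10 — 39 cells in total.
_GRID_ROWS = [
    (10, 20, 33.69, 4.98),
    (10, 30, 59.80, 7.25),
    (10, 40, 83.28, 8.55),
    (10, 50, 104.77, 10.04),
    (10, 60, 129.02, 11.61),
    (10, 70, 153.48, 12.96),
    (10, 80, 180.18, 16.15),
    (10, 90, 215.12, 20.88),
    (10, 100, 258.89, 30.68),
    (20, 30, 26.20, 4.95),
    (20, 40, 50.33, 6.94),
    (20, 50, 72.64, 9.19),
    (20, 60, 95.99, 11.02),
    (20, 70, 120.95, 12.44),
    (20, 80, 149.72, 16.23),
    (20, 90, 183.13, 21.97),
    (20, 100, 224.22, 29.84),
    (30, 40, 24.12, 4.99),
    (30, 50, 46.88, 7.11),
    (30, 60, 69.35, 10.07),
    (30, 70, 94.82, 11.98),
    (30, 80, 124.13, 15.83),
    (30, 90, 154.76, 20.17),
    (30, 100, 196.72, 25.73),
    (40, 50, 24.03, 5.56),
    (40, 60, 47.46, 8.32),
    (40, 70, 71.54, 10.95),
    (40, 80, 99.57, 14.64),
    (40, 90, 131.79, 19.80),
    (40, 100, 173.17, 27.81),
    (50, 60, 23.64, 6.04),
    (50, 70, 48.13, 9.12),
    (50, 80, 76.71, 14.77),
    (50, 90, 108.89, 18.16),
    (50, 100, 153.79, 26.23),
    (60, 70, 25.77, 7.46),
    (60, 80, 54.70, 12.85),
    (60, 90, 86.83, 17.49),
    (60, 100, 127.88, 26.77),
]

WAITING_TIME_GRID: tuple[FPTTriple, ...] = tuple(
    FPTTriple(v0=float(v0), vc=float(vc), mu=mu, sigma=sd) for v0, vc, mu, sd in _GRID_ROWS
)

SEATTLE_RECORDS: tuple[PatientRecord, ...] = (
    PatientRecord(patient_id="U3863224", v1=1.592, dt=13.0, v2=2.715),
    PatientRecord(patient_id="U2223925", v1=20.83, dt=16.0, v2=34.77),
    PatientRecord(patient_id="U4348415", v1=17.27, dt=30.0, v2=29.76),
)
"""Independently collected paired-scan records (ellipsoid volume estimates)."""
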