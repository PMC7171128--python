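#!/usr/bin/env python
"""Condense the waiting-time grid into closed-form survival surfaces.

The grid means are fitted by a plane mu(v0, vc) and the grid SDs by a
restricted quadratic sigma(v0, vc); together they turn any (current volume,
death volume) pair into a normal survival-time distribution.  Prints the
fitted coefficients next to the published ones.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gbmgrowth.model_fit import FPTTriple, fit_mean_surface, fit_sd_surface
from gbmgrowth.reference import PUBLISHED_MEAN_SURFACE, PUBLISHED_SD_SURFACE
from gbmgrowth.survival_calc import SurvivalSurfaces


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--grid", type=Path, default=Path("results/fpt_grid.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.grid)
    triples = [
        FPTTriple(v0=r.v0_ml, vc=r.vc_ml, mu=r.mean_days, sigma=r.sd_days)
        for r in df.itertuples()
    ]
    surfaces = SurvivalSurfaces(
        mean=fit_mean_surface(triples), sd=fit_sd_surface(triples)
    )

    print("mean surface (days):       fitted    published")
    for name in ("beta0", "beta_v0", "beta_vc"):
        print(f"  {name:>8}: {getattr(surfaces.mean, name):>12.4g} "
              f"{getattr(PUBLISHED_MEAN_SURFACE, name):>12.4g}")
    print("SD surface (days):")
    for name in ("gamma0", "gamma_v0", "gamma_vc", "gamma_v0vc", "gamma_vc2"):
        print(f"  {name:>10}: {getattr(surfaces.sd, name):>12.4g} "
              f"{getattr(PUBLISHED_SD_SURFACE, name):>12.4g}")

    out = args.out_dir / "surfaces.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(surfaces.to_dict(), indent=2, sort_keys=True))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
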