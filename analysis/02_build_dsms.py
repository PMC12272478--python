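"""Unwrap the simulated cohort into normalized EQD2 dose-surface maps.

Reads the bundle written by 01_simulate_cohort.py, spherically unwraps each
bladder onto the 91x90 lattice, converts to EQD2 (alpha/beta = 1 Gy), and
exports the first few patients' maps as CSV plus a cohort-mean map figure.
"""

from pathlib import Path

import numpy as np

from drmap.eqd2 import FractionationContext, eqd2_dsm
from drmap.geometry import unwrap_bladder_spherical
from drmap.io import load_cohort, save_dsm_csv
from drmap.plotting import plot_drm

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "cohort_bladder.h5"
OUT = ROOT / "results" / "dsms"


def main() -> None:
    if not BUNDLE.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    patients = load_cohort(BUNDLE)
    maps = []
    for i, p in enumerate(patients):
        ctx = FractionationContext(n_fractions=p.n_fractions, alpha_beta=1.0)
        dsm = eqd2_dsm(unwrap_bladder_spherical(p.contours, p.dose), ctx)
        maps.append(dsm)
        if i < 5:
            save_dsm_csv(OUT / f"patient_{i:03d}_eqd2.csv", dsm)

    stack = np.stack([m.doses for m in maps])
    valid = np.logical_and.reduce([m.valid for m in maps])
    mean_map = np.where(valid, stack.mean(0), np.nan)
    plot_drm(mean_map, np.zeros_like(valid), organ="bladder",
             path=OUT / "cohort_mean_eqd2.png", title="cohort mean EQD2")
    print(f"unwrapped {len(maps)} patients; "
          f"mean-map range {np.nanmin(mean_map):.1f}-{np.nanmax(mean_map):.1f} Gy; "
          f"{int(valid.sum())}/8190 voxels valid in every patient")


if __name__ == "__main__":
    main()
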