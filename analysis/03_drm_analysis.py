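"""Full dose-response mapping run: both dichotomization methods, permutation
Tmax significance, and the without/with-baseline-correction comparison.

Runs the end-to-end pipeline on the simulated cohort spec (regenerated
deterministically, so 01/02 need not have run), with 1000 permutations at
the 95th percentile, and prints the per-endpoint comparison table: event
counts, significant-voxel counts and Dice overlap between the two methods'
high-risk subregions.
"""

from pathlib import Path

from drmap.cohort import CohortSpec
from drmap.pipeline import RunConfig, compare_methods, run_drm_analysis

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "drm"


def main() -> None:
    spec = CohortSpec(n_patients=80, seed=42)
    cfg = RunConfig(cohort=spec, n_iterations=1000, percentile=95.0,
                    tails="both", seed=7, out_dir=str(OUT), make_plots=True)
    summary = run_drm_analysis(cfg)
    table = compare_methods(summary)
    print(table.to_string(index=False))
    print(f"\nartifacts in {OUT} (t-maps, Tmax samples, masks, figures)")
    subset_ok = (table["events_corr"] <= table["events_uncorr"]).all()
    print(f"corrected event counts <= uncorrected on every endpoint: {subset_ok}")


if __name__ == "__main__":
    main()
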