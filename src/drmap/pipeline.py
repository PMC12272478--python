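"""End-to-end orchestration: simulate -> unwrap -> normalize -> EQD2 ->
label -> permutation inference -> method comparison.

Everything here is a thin, reproducible driver over the library modules; the
numbered scripts under ``analysis/`` and the click CLI call these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, SyntheticPatient, generate_cohort
from .conventions import DegenerateGroupsError, N_COLS, N_ROWS
from .eqd2 import FractionationContext, eqd2_dsm
from .geometry import normalize_dsm, unwrap_bladder_spherical, unwrap_rectum_cylindrical
from .io import load_cohort, toxicity_table
from .toxicity import METHODS, label_cohort, split_cohort
from .voxelstats import count_significant, dsc, permutation_tmax, shapiro_screen

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_drm_analysis", "compare_methods"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one dose-response mapping run."""

    cohort: CohortSpec | None = None
    bundle_path: str | None = None
    alpha_beta: float = 1.0
    endpoints: tuple | None = None          # None -> all endpoints in the cohort
    methods: tuple = METHODS
    n_iterations: int = 1000
    percentile: float = 95.0
    tails: str = "both"
    statistic: str = "welch"
    grade_cutpoint: int = 1
    seed: int = 0
    out_dir: str | None = None
    run_shapiro: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.bundle_path is None):
            raise ValueError("provide exactly one of cohort spec or bundle path")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be positive")
        if self.tails not in ("upper", "lower", "both"):
            raise ValueError("tails must be upper/lower/both")
        if self.statistic not in ("welch", "mannwhitney"):
            raise ValueError("statistic must be welch or mannwhitney")
        bad = set(self.methods) - set(METHODS)
        if bad or not self.methods:
            raise ValueError(f"unknown methods {bad or self.methods}")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be >= 100")


def _patient_dsms(patients: list[SyntheticPatient], cfg: RunConfig):
    """Unwrap, normalize and EQD2-convert every patient's surface map."""
    dsms = []
    for i, p in enumerate(patients):
        t0 = time.perf_counter()
        if p.contours.organ == "bladder":
            dsm = unwrap_bladder_spherical(p.contours, p.dose)
        else:
            dsm = normalize_dsm(unwrap_rectum_cylindrical(p.contours, p.dose),
                                organ="rectum")
        ctx = FractionationContext(n_fractions=p.n_fractions,
                                   alpha_beta=cfg.alpha_beta)
        dsms.append(eqd2_dsm(dsm, ctx))
        log.debug("patient %d unwrapped in %.2f s", i, time.perf_counter() - t0)
    return dsms


def run_drm_analysis(cfg: RunConfig) -> dict:
    """Run the full analysis and return (and optionally write) the summary.

    For each endpoint x dichotomization method: split the cohort, compute
    the voxel statistic map, the permutation Tmax thresholds and the
    significance masks; for each endpoint analysed under both methods, the
    Dice overlap of the two masks.  Numeric outputs are byte-identical for
    identical configs (per-analysis seeds derive from ``cfg.seed``).
    """
    t_start = time.perf_counter()
    if cfg.cohort is not None:
        patients = generate_cohort(cfg.cohort, alpha_beta=cfg.alpha_beta)
    else:
        patients = load_cohort(cfg.bundle_path)

    dsms = _patient_dsms(patients, cfg)
    endpoints = cfg.endpoints or tuple(
        dict.fromkeys(r.endpoint for p in patients for r in p.toxicity))

    summary: dict = {
        "config": _config_dict(cfg),
        "n_patients": len(patients),
        "endpoints": {},
    }
    masks: dict = {}
    for ep in endpoints:
        ep_summary: dict = {"methods": {}}
        for mi, method in enumerate(cfg.methods):
            records = []
            for p in patients:
                rec = next((r for r in p.toxicity if r.endpoint == ep), None)
                if rec is not None:
                    records.append(rec)
            labels, excluded = label_cohort(records, method,
                                            cutpoint=cfg.grade_cutpoint)
            # align DSMs with surviving labels by patient id
            id_to_dsm = {p.toxicity[0].patient_id: d
                         for p, d in zip(patients, dsms)}
            ep_dsms = [id_to_dsm[l.patient_id] for l in labels]
            n_events = sum(l.event for l in labels)
            m_summary = {
                "n_analysed": len(labels),
                "n_excluded": len(excluded),
                "n_events": n_events,
                "n_nonevents": len(labels) - n_events,
            }
            seed = int(np.random.SeedSequence(
                entropy=cfg.seed,
                spawn_key=(endpoints.index(ep), mi)).generate_state(1)[0] % (2 ** 31))
            try:
                event_dsms, nonevent_dsms = split_cohort(ep_dsms, labels)
                perm = permutation_tmax(
                    ep_dsms, labels, statistic=cfg.statistic,
                    n_iterations=cfg.n_iterations, percentile=cfg.percentile,
                    seed=seed, tails=cfg.tails)
            except DegenerateGroupsError as exc:
                m_summary["refused"] = str(exc)
                ep_summary["methods"][method] = m_summary
                log.warning("endpoint %s / %s refused: %s", ep, method, exc)
                continue
            m_summary.update({
                "threshold_upper": perm.threshold_upper,
                "threshold_lower": perm.threshold_lower,
                "n_significant_high": count_significant(perm.sig_mask_high),
                "n_significant_low": count_significant(perm.sig_mask_low),
                "n_significant": count_significant(perm.sig_mask),
                "n_valid_voxels": int(perm.observed.valid.sum()),
                "seed": seed,
            })
            if cfg.run_shapiro:
                scr_e = shapiro_screen(event_dsms)
                scr_n = shapiro_screen(nonevent_dsms)
                m_summary["shapiro_failing_fraction"] = {
                    "event": scr_e.failing_fraction,
                    "nonevent": scr_n.failing_fraction,
                }
            masks[(ep, method)] = perm
            ep_summary["methods"][method] = m_summary
        if all((ep, m) in masks for m in cfg.methods) and len(cfg.methods) == 2:
            a = masks[(ep, cfg.methods[0])].sig_mask
            b = masks[(ep, cfg.methods[1])].sig_mask
            r = dsc(a, b)
            ep_summary["dsc"] = {"value": r.dsc, "n_a": r.n_a, "n_b": r.n_b,
                                 "n_intersection": r.n_intersection}
        summary["endpoints"][ep] = ep_summary

    summary["runtime_s"] = round(time.perf_counter() - t_start, 3)
    if cfg.out_dir is not None:
        _write_outputs(cfg, summary, masks, patients)
    summary["_permutation_results"] = masks  # in-memory only, never serialized
    return summary


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d["cohort"] is not None:
        d["cohort"]["planted_region"] = [list(rc) for rc in d["cohort"]["planted_region"]]
    return d


def _write_outputs(cfg: RunConfig, summary: dict, masks: dict, patients) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(_config_dict(cfg), indent=1))
    clean = {k: v for k, v in summary.items() if not k.startswith("_")}
    (out / "summary.json").write_text(json.dumps(clean, indent=1))
    toxicity_table(patients).to_csv(out / "toxicity.csv", index=False)
    for (ep, method), perm in masks.items():
        stem = f"{ep}__{method}"
        np.savetxt(out / f"{stem}_tmap.csv", perm.observed.t, delimiter=",",
                   fmt="%.6g")
        np.savetxt(out / f"{stem}_tmax_samples.csv", perm.tmax_samples,
                   delimiter=",", fmt="%.6g")
        np.savetxt(out / f"{stem}_sigmask.csv", perm.sig_mask.astype(int),
                   delimiter=",", fmt="%d")
        if cfg.make_plots:
            from .plotting import plot_drm
            from .voxelstats import stack_maps
            dsm_stack, valid = stack_maps([p.dsm for p in patients
                                           if p.dsm is not None])
            mean_map = np.nanmean(np.where(valid, dsm_stack, np.nan), axis=0)
            plot_drm(mean_map, perm.sig_mask, organ=patients[0].contours.organ,
                     path=out / f"{stem}_drm.png",
                     title=f"{ep} ({method})")


def compare_methods(summary: dict) -> pd.DataFrame:
    """Per-endpoint comparison table in the without/with reporting format:
    events, significant voxel counts and Dice overlap per method pair."""
    rows = []
    for ep, s in summary["endpoints"].items():
        m = s["methods"]
        row = {"endpoint": ep}
        for method, stats_ in m.items():
            key = "uncorr" if method == "uncorrected" else "corr"
            row[f"events_{key}"] = stats_.get("n_events")
            row[f"voxels_{key}"] = stats_.get("n_significant")
        row["dsc"] = s.get("dsc", {}).get("value")
        rows.append(row)
    return pd.DataFrame(rows)
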