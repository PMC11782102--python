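"""End-to-end case and cohort processing.

``compute_case`` runs the full measurement on one pancreas/duct mask
pair: centerline estimation, smoothing/resampling/framing, per-section
DP ratios, and the percentile score.  ``run_cohort`` maps it over a
case table and attaches the evaluation statistics.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .centerline import estimate_centerline
from .cohort_stats import (CohortTable, roc_auroc, select_thresholds,
                           three_group_comparison, welch_t_test)
from .config import RunConfig
from .curve_geometry import frames_for_centerline
from .dp_ratio import DPRatioProfile, dp_profile
from .mask_io import VoxelMask, check_pair, read_mask

__all__ = ["CaseResult", "compute_case", "compute_case_from_masks",
           "run_cohort", "evaluate_cohort"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CaseResult:
    case_id: str
    profile: DPRatioProfile
    score: float
    config: RunConfig

    def report(self) -> dict:
        report = self.profile.case_report(self.case_id)
        report["config"] = self.config.to_dict()
        return report


def compute_case_from_masks(pancreas: VoxelMask, duct: VoxelMask,
                            config: RunConfig | None = None,
                            case_id: str = "") -> CaseResult:
    """Measurement pipeline on in-memory masks."""
    config = config or RunConfig()
    check_pair(pancreas, duct)
    t0 = time.perf_counter()
    centerline = estimate_centerline(pancreas, exponent=config.dijkstra_exponent)
    t1 = time.perf_counter()
    frames = frames_for_centerline(
        centerline.points,
        smoothing_half_width=config.smoothing_half_width,
        step=config.resample_step_mm,
        lookahead=config.tangent_lookahead_mm)
    profile = dp_profile(
        pancreas, duct, frames,
        half_extent=config.section_half_extent_mm,
        in_plane_step=config.in_plane_step_mm,
        along_step=config.resample_step_mm,
        denominator=config.denominator_convention,
        score_percentile=config.percentile_level)
    t2 = time.perf_counter()
    logger.info("case %s: centerline %.1fs, profile %.1fs (%d sections, %d valid)",
                case_id or "<unnamed>", t1 - t0, t2 - t1,
                len(profile.arc_s), profile.n_valid)
    return CaseResult(case_id=case_id, profile=profile,
                      score=profile.score, config=config)


def compute_case(pancreas_path, duct_path, config: RunConfig | None = None,
                 case_id: str = "") -> CaseResult:
    """Measurement pipeline on mask files (NIfTI or MetaImage)."""
    pancreas = read_mask(pancreas_path, "pancreas")
    duct = read_mask(duct_path, "mpd")
    return compute_case_from_masks(pancreas, duct, config,
                                   case_id or Path(str(pancreas_path)).stem)


def evaluate_cohort(cohort: CohortTable, alpha: float = 0.05,
                    min_rate: float = 0.90) -> dict:
    """Detection statistics of the score for each imaging finding."""
    df = cohort.table
    out: dict = {"n_cases": int(len(df)), "alpha": alpha, "findings": {}}
    for finding in ("mpdd", "ppa"):
        labels = df[finding].to_numpy(dtype=bool)
        scores = df["score"].to_numpy(dtype=float)
        entry: dict = {
            "n_positive": int(labels.sum()),
            "n_negative": int((~labels).sum()),
        }
        if labels.all() or not labels.any():
            entry["skipped"] = ("no positive cases" if not labels.any()
                                else "no negative cases")
            out["findings"][finding] = entry
            logger.warning("finding %s: statistics skipped (%s)",
                           finding, entry["skipped"])
            continue
        pos, neg = scores[labels], scores[~labels]
        entry["mean_positive"] = float(pos.mean())
        entry["range_positive"] = [float(pos.min()), float(pos.max())]
        entry["mean_negative"] = float(neg.mean())
        entry["range_negative"] = [float(neg.min()), float(neg.max())]
        try:
            welch = welch_t_test(pos, neg)
            entry["welch"] = {"t": welch.t, "df": welch.df, "p": welch.p,
                              "significant": welch.significant(alpha)}
        except ValueError as exc:  # e.g. degenerate zero-variance groups
            entry["welch"] = {"error": str(exc)}
            logger.warning("finding %s: Welch test not computable (%s)",
                           finding, exc)
        roc = roc_auroc(scores, labels)
        entry["auroc"] = roc.auroc
        op_sens, op_spec = select_thresholds(scores, labels, min_rate=min_rate)
        entry["operating_points"] = {
            f"sensitivity_ge_{min_rate:g}": dataclasses.asdict(op_sens),
            f"specificity_ge_{min_rate:g}": dataclasses.asdict(op_spec),
        }
        out["findings"][finding] = entry

    groups_ok = (
        (df["mpdd"] & df["ppa"]).sum() >= 2
        and (df["mpdd"] & ~df["ppa"]).sum() >= 2
        and (~df["mpdd"] & ~df["ppa"]).sum() >= 2
    )
    if groups_ok:
        out["three_group"] = three_group_comparison(cohort, alpha=alpha)
    else:
        out["three_group"] = {"skipped": "need >= 2 cases in each of the three groups"}
    return out


def run_cohort(case_table: pd.DataFrame, config: RunConfig | None = None
               ) -> tuple[CohortTable, dict]:
    """Score every case in a table with columns
    (case_id, pancreas_path, duct_path, mpdd, ppa); failing cases are
    logged and excluded rather than aborting the run."""
    config = config or RunConfig()
    records, failures = [], []
    for row in case_table.itertuples(index=False):
        try:
            result = compute_case(row.pancreas_path, row.duct_path, config,
                                  case_id=str(row.case_id))
            records.append({"case_id": str(row.case_id), "score": result.score,
                            "mpdd": bool(row.mpdd), "ppa": bool(row.ppa)})
        except Exception as exc:  # noqa: BLE001 - screening robustness
            failures.append(str(row.case_id))
            logger.error("case %s failed: %s", row.case_id, exc)
    if not records:
        raise ValueError("every case in the cohort failed")
    cohort = CohortTable(pd.DataFrame.from_records(records))
    evaluation = evaluate_cohort(cohort, alpha=config.alpha)
    evaluation["n_failed"] = len(failures)
    evaluation["failed_cases"] = failures
    return cohort, evaluation
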