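"""Patient- and sextant-level scoring, ROC sweeps over alpha, and the TCL grid search.

A patient is predicted EPE-positive iff the final map ``Q`` has any
nonzero voxel; a sextant is positive iff ``Q`` (or the ground-truth EPE
labelmap) has any nonzero voxel inside that sextant's whole-grid region.
ROC curves are built by sweeping the binary threshold alpha over
[0, 1] in steps of 0.05, re-running the decision pipeline at each value
and pooling confusion counts across the cohort at each level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .epe_pipeline import PipelineParams, apply_mask, capsule_contours, detect_epe, dilate_mask
from .sextants import partition, region_flags
from .volio import Volume3D

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "EvalCase",
    "patient_call",
    "flags_to_list",
    "confusion",
    "sens_spec",
    "auc",
    "roc_sweep",
    "sweep_case_predictions",
    "roc_from_flags",
    "grid_search_tcl",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_TCL_GRID",
]

#: alpha in [0, 1] in steps of 0.05 — 21 values
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0, 21) * 0.05, 2))

#: the standard TCL-threshold search grid, mm
DEFAULT_TCL_GRID: tuple[float, ...] = (2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class ROCCurve:
    """Threshold-sweep operating points and their trapezoidal AUC."""

    points: list[tuple[float, float, float]]  # (alpha, tpr, fpr)
    auc: float | None
    level: str  # "patient" or "sextant"


@dataclass
class EvalCase:
    """One cohort case: probability map, prostate mask, ground-truth EPE labels."""

    p_ca: Volume3D
    prostate: Volume3D
    gt_epe: Volume3D
    case_id: str = ""


def flags_to_list(flags: dict[int, bool]) -> list[bool]:
    """Sextant flag dict -> list in ascending label order (stable unit order)."""
    return [flags[lab] for lab in sorted(flags)]


def patient_call(q: Volume3D) -> bool:
    """Patient-level prediction: positive iff Q is nonzero anywhere."""
    return bool(np.any(q.data != 0))


def confusion(pred: Sequence[bool], gt: Sequence[bool]) -> ConfusionCounts:
    """Confusion counts over paired binary calls (patients or sextants)."""
    if len(pred) != len(gt):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(gt)} labels")
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & gt)),
        fp=int(np.sum(pred & ~gt)),
        tn=int(np.sum(~pred & ~gt)),
        fn=int(np.sum(~pred & gt)),
    )


def sens_spec(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """(sensitivity, specificity); a component with zero denominator is None."""
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return sens, spec


def auc(points: Sequence[tuple[float, float]] | ROCCurve) -> float:
    """Trapezoidal area under (fpr, tpr) points, augmented with (0,0) and (1,1).

    Points are sorted by fpr (ties by tpr); invariant to input order.
    """
    if isinstance(points, ROCCurve):
        pts = [(fpr, tpr) for _, tpr, fpr in points.points]
    else:
        pts = [(float(f), float(t)) for f, t in points]
    pts = sorted(set(pts + [(0.0, 0.0), (1.0, 1.0)]))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def sweep_case_predictions(
    p_ca: Volume3D,
    prostate: Volume3D,
    params: PipelineParams,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
) -> tuple[list[bool], list[dict[int, bool]]]:
    """Per-alpha patient and sextant predictions for one case.

    The alpha-independent stages (mask dilation, masking, capsule
    contours, sextant partition) are computed once and shared across the
    sweep; returns ``(patient_flags, sextant_flags)`` parallel to
    ``alphas``.
    """
    m_pr = dilate_mask(prostate, params.dilation_radius)
    masked = apply_mask(p_ca, m_pr)
    contours = capsule_contours(prostate)
    part = partition(prostate)
    patient_flags: list[bool] = []
    sextant_flags: list[dict[int, bool]] = []
    for a in alphas:
        pa = PipelineParams(
            alpha=float(a),
            tcl_threshold=params.tcl_threshold,
            dilation_radius=params.dilation_radius,
            tcl_strict=params.tcl_strict,
        )
        q, _ = detect_epe(p_ca, prostate, pa, _masked=masked, _contours=contours)
        patient_flags.append(patient_call(q))
        sextant_flags.append(region_flags(q, part))
    return patient_flags, sextant_flags


def _gt_flags(case: EvalCase) -> tuple[bool, dict[int, bool]]:
    part = partition(case.prostate)
    return bool(np.any(case.gt_epe.data != 0)), region_flags(case.gt_epe, part)


def roc_from_flags(
    alphas: Sequence[float],
    pred_flags: list[list[bool]],
    gt: list[bool],
    level: str,
) -> ROCCurve:
    """Build an ROC curve from per-alpha pooled binary predictions.

    ``pred_flags[i]`` holds the predictions of all units at ``alphas[i]``;
    ``gt`` the matching ground truth.  AUC is None when the cohort lacks
    positive or negative units at this level.
    """
    gt_arr = np.asarray(gt, dtype=bool)
    points = []
    for a, preds in zip(alphas, pred_flags):
        c = confusion(preds, gt)
        sens, spec = sens_spec(c)
        tpr = sens if sens is not None else np.nan
        fpr = (1.0 - spec) if spec is not None else np.nan
        points.append((float(a), tpr, fpr))
    if gt_arr.any() and not gt_arr.all():
        a = auc([(fpr, tpr) for _, tpr, fpr in points])
    else:
        a = None
    return ROCCurve(points=points, auc=a, level=level)


def roc_sweep(
    cases: Sequence[EvalCase],
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    params: PipelineParams | None = None,
) -> tuple[ROCCurve, ROCCurve]:
    """Patient- and sextant-level ROC curves over the alpha grid.

    For each alpha, the decision pipeline runs on every case; confusion
    counts are pooled across the cohort at each level (sextant units are
    pooled across patients, six per patient).
    """
    if not cases:
        raise ValueError("need at least one case")
    params = params or PipelineParams()
    n_alpha = len(grid)
    patient_preds: list[list[bool]] = [[] for _ in range(n_alpha)]
    sextant_preds: list[list[bool]] = [[] for _ in range(n_alpha)]
    patient_gt: list[bool] = []
    sextant_gt: list[bool] = []
    for case in cases:
        pf, sf = sweep_case_predictions(case.p_ca, case.prostate, params, grid)
        g_pat, g_sex = _gt_flags(case)
        patient_gt.append(g_pat)
        sextant_gt.extend(g_sex[lab] for lab in sorted(g_sex))
        for i in range(n_alpha):
            patient_preds[i].append(pf[i])
            sextant_preds[i].extend(sf[i][lab] for lab in sorted(sf[i]))
    return (
        roc_from_flags(grid, patient_preds, patient_gt, "patient"),
        roc_from_flags(grid, sextant_preds, sextant_gt, "sextant"),
    )


def grid_search_tcl(
    cases: Sequence[EvalCase],
    tcl_values: Sequence[float] = DEFAULT_TCL_GRID,
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    params: PipelineParams | None = None,
    folds: Sequence[Sequence[int]] | None = None,
) -> pd.DataFrame:
    """AUC at patient and sextant level for each TCL threshold.

    With ``folds`` (lists of case indices), one ROC sweep per fold is run
    at each TCL value and the mean AUC over folds is tabulated; otherwise
    the whole cohort is one fold.  Returns a DataFrame with columns
    ``tcl_mm``, ``patient_auc``, ``sextant_auc``.
    """
    if not tcl_values:
        raise ValueError("tcl_values must be nonempty")
    params = params or PipelineParams()
    if folds is None:
        folds = [list(range(len(cases)))]
    rows = []
    for tcl in tcl_values:
        p = PipelineParams(
            alpha=params.alpha,
            tcl_threshold=float(tcl),
            dilation_radius=params.dilation_radius,
            tcl_strict=params.tcl_strict,
        )
        pat_aucs, sex_aucs = [], []
        for fold in folds:
            fold_cases = [cases[i] for i in fold]
            roc_pat, roc_sex = roc_sweep(fold_cases, grid, p)
            if roc_pat.auc is not None:
                pat_aucs.append(roc_pat.auc)
            if roc_sex.auc is not None:
                sex_aucs.append(roc_sex.auc)
        rows.append(
            {
                "tcl_mm": float(tcl),
                "patient_auc": float(np.mean(pat_aucs)) if pat_aucs else np.nan,
                "sextant_auc": float(np.mean(sex_aucs)) if sex_aucs else np.nan,
            }
        )
    return pd.DataFrame(rows)
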