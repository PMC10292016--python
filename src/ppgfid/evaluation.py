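"""Detector evaluation: per-point matching and the four summary metrics.

A detected landmark counts as a true positive when it lies within a time
tolerance (10 ms by default) of the same-named reference landmark; a
mislocated point is counted as both a spurious detection (FP) and a miss
(FN) unless ``mislocated_fp_only`` is set.  From the pooled counts:

    Acc = 100 * TP / (TP + FP + FN)        accuracy
    Err = 100 * (FP + FN) / TFP            error rate
    S   = 100 * TP / (TP + FN)             sensitivity
    PP  = 100 * TP / (TP + FP)             positive predictivity

where TFP is the total number of reference fiducial points (14 per
complete beat).  Reports are stratified by the c/d morphology regime
with a pooled row computed from summed counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, UndefinedMetricError
from .fiducials import POINT_NAMES, FiducialSet

__all__ = [
    "EvalCounts",
    "Metrics",
    "POINTS_PER_BEAT",
    "match_points",
    "counts_from_labels",
    "compute_metrics",
    "stratified_report",
    "evaluate_extraction",
    "round_half_away",
]

POINTS_PER_BEAT = len(POINT_NAMES)  # 14
TOLERANCE_S_DEFAULT = 0.010


@dataclass
class EvalCounts:
    """TP/FP/FN tallies against a total of ``tfp`` reference points."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tfp: int = 0
    n_subjects: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tfp + other.tfp,
            self.n_subjects + other.n_subjects,
        )


@dataclass
class Metrics:
    """The four percentages derived from one set of counts."""

    acc: float
    err: float
    sensitivity: float
    positive_predictivity: float


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (display convention)."""
    factor = 10.0**ndigits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def match_points(
    detected: FiducialSet,
    reference: dict[str, int | None],
    tol: float = TOLERANCE_S_DEFAULT,
    fs: float = 1000.0,
    mislocated_fp_only: bool = False,
) -> dict[str, str]:
    """Label each landmark TP, FP or FN by name-wise tolerance matching.

    ``reference`` maps point names to reference sample indices (``None``
    for points absent from the reference).  Matching never crosses point
    names.  A mislocated detection yields ``"FP+FN"`` (or ``"FP"`` when
    ``mislocated_fp_only``).
    """
    if tol <= 0:
        raise ParameterError(f"tolerance must be positive, got {tol}")
    unknown = set(reference) - set(POINT_NAMES)
    if unknown:
        raise FormatError(f"unknown point names in reference: {sorted(unknown)}")
    tol_samples = tol * fs
    labels: dict[str, str] = {}
    for name in POINT_NAMES:
        ref = reference.get(name)
        ref = None if ref is None or (isinstance(ref, float) and np.isnan(ref)) else int(ref)
        det = detected.indices.get(name) if detected.valid else None
        if det is None and ref is None:
            continue
        if det is None:
            labels[name] = "FN"
        elif ref is None:
            labels[name] = "FP"
        elif abs(det - ref) <= tol_samples:
            labels[name] = "TP"
        else:
            labels[name] = "FP" if mislocated_fp_only else "FP+FN"
    return labels


def counts_from_labels(labels: dict[str, str], tfp: int, n_subjects: int = 1) -> EvalCounts:
    """Collapse per-point labels into an :class:`EvalCounts`."""
    tp = sum(1 for v in labels.values() if v == "TP")
    fp = sum(1 for v in labels.values() if "FP" in v)
    fn = sum(1 for v in labels.values() if "FN" in v)
    return EvalCounts(tp=tp, fp=fp, fn=fn, tfp=tfp, n_subjects=n_subjects)


def compute_metrics(counts: EvalCounts) -> Metrics:
    """The four percentages from one set of counts (raw doubles)."""
    denom_acc = counts.tp + counts.fp + counts.fn
    if denom_acc == 0 or counts.tfp == 0:
        raise UndefinedMetricError("no attempted points: metrics undefined")
    if counts.tp + counts.fn == 0 or counts.tp + counts.fp == 0:
        raise UndefinedMetricError("zero denominator in sensitivity or positive predictivity")
    return Metrics(
        acc=100.0 * counts.tp / denom_acc,
        err=100.0 * (counts.fp + counts.fn) / counts.tfp,
        sensitivity=100.0 * counts.tp / (counts.tp + counts.fn),
        positive_predictivity=100.0 * counts.tp / (counts.tp + counts.fp),
    )


def evaluate_extraction(
    result,
    reference: pd.DataFrame,
    tol: float = TOLERANCE_S_DEFAULT,
    mislocated_fp_only: bool = False,
) -> pd.DataFrame:
    """Score a pipeline run against a reference annotation table.

    ``result`` is an :class:`~ppgfid.extractor.ExtractionResult`;
    ``reference`` holds one row per subject with the 14 point columns in
    record coordinates (0-based) and, optionally, a ``case`` column that
    is ignored here — stratification uses the morphology regime the
    detector assigned.  Detected segment-relative indices are shifted by
    each subject's Min1 onset before matching.  Returns the stratified
    report of :func:`stratified_report`.
    """
    per_subject: list[tuple[str, EvalCounts]] = []
    common = 0
    for r in result.results:
        if r.subject_id not in reference.index:
            continue
        common += 1
        row = reference.loc[r.subject_id]
        ref = {p: row[p] for p in POINT_NAMES}
        det = FiducialSet(valid=False)
        if r.ok:
            det = FiducialSet(
                indices={
                    k: (v + r.min1 if v is not None else None)
                    for k, v in r.fiducials.indices.items()
                },
                case_label=r.fiducials.case_label,
                cd_present=r.fiducials.cd_present,
            )
        labels = match_points(det, ref, tol=tol, fs=result.fs,
                              mislocated_fp_only=mislocated_fp_only)
        n_ref = sum(1 for p in POINT_NAMES if not pd.isna(row[p]))
        counts = counts_from_labels(labels, tfp=n_ref, n_subjects=1)
        per_subject.append((det.case_label if r.ok else "II", counts))
    if common == 0:
        raise ParameterError("no overlapping subject ids between detections and reference")
    return stratified_report(per_subject)


def stratified_report(per_subject: list[tuple[str, EvalCounts]]) -> pd.DataFrame:
    """Per-regime metric rows plus a pooled row from summed counts.

    ``per_subject`` pairs each subject's morphology label (``"I"``,
    ``"II"``, ``"III"``) with its counts.  Regimes with no subjects are
    omitted.  Percentages are reported as raw doubles; round for display
    with :func:`round_half_away`.
    """
    if not per_subject:
        raise ParameterError("nothing to report")
    rows = []
    pooled = EvalCounts()
    for case in ("I", "II", "III"):
        total = EvalCounts()
        for label, counts in per_subject:
            if label == case:
                total = total + counts
        if total.n_subjects == 0 and total.tfp == 0:
            continue
        pooled = pooled + total
        rows.append((case, total))
    rows.append(("pooled", pooled))
    out = []
    for label, counts in rows:
        m = compute_metrics(counts)
        out.append(
            {
                "case": label,
                "N": counts.n_subjects,
                "TFP": counts.tfp,
                "TP": counts.tp,
                "FP": counts.fp,
                "FN": counts.fn,
                "S_pct": m.sensitivity,
                "PP_pct": m.positive_predictivity,
                "Err_pct": m.err,
                "Acc_pct": m.acc,
            }
        )
    return pd.DataFrame(out).set_index("case")
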