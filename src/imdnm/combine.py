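"""Combined multimodal index and surgical-outcome evaluation.

The combined index of a region is the plain average of its iEEG source-sink
score and its fMRI outbound-excitation score (both already normalized to
[0, 1] within the patient).  Patient-level scores are unweighted means over
the patient's evaluated regions.  Separation of good (Engel I-II) from poor
(Engel III-IV) outcomes is assessed by scanning a decision threshold over
[0, 1] and reporting sensitivity, specificity and balanced accuracy; the
reported optimal threshold maximizes balanced accuracy (smallest threshold
on ties).  Balanced accuracy is used because surgical cohorts are typically
imbalanced toward good outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import RoiMask

__all__ = [
    "combine",
    "patient_scores",
    "threshold_scan",
    "overlap_analysis",
    "modality_correlation",
    "EvaluationResult",
]

logger = logging.getLogger(__name__)

GOOD_OUTCOMES = frozenset({"I", "II"})
POOR_OUTCOMES = frozenset({"III", "IV"})

SCORE_COLUMNS = ("score_ieeg", "score_fmri", "score_combined")


def combine(scores: pd.DataFrame) -> pd.DataFrame:
    """Add ``score_combined = (score_ieeg + score_fmri) / 2`` per region.

    ``scores`` must carry ``patient_id``, ``roi_id``, ``score_ieeg`` and
    ``score_fmri`` columns; rows missing either modality get a missing
    combined score and ``combined_missing = True``.
    """
    out = scores.copy()
    if out.duplicated(subset=["patient_id", "roi_id"]).any():
        raise ValueError("duplicate (patient_id, roi_id) rows in score table")
    for c in ("score_ieeg", "score_fmri"):
        present = out[c].dropna()
        if ((present < 0) | (present > 1)).any():
            raise ValueError(f"{c} values outside [0, 1]")
    both = out["score_ieeg"].notna() & out["score_fmri"].notna()
    out["score_combined"] = np.where(
        both, (out["score_ieeg"] + out["score_fmri"]) / 2.0, np.nan
    )
    out["combined_missing"] = ~both
    n_miss = int((~both).sum())
    if n_miss:
        logger.info("%d region(s) missing a modality; combined score absent", n_miss)
    return out


def patient_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-patient mean of each modality over its scored regions.

    Patients with no scored region for a modality carry NaN there; patients
    with no rows at all are simply absent (and logged).
    """
    cols = [c for c in SCORE_COLUMNS if c in scores.columns]
    table = scores.groupby("patient_id")[cols].mean()
    empty = table[cols].isna().all(axis=1)
    if empty.any():
        logger.info("patients without any scored region: %s", list(table.index[empty]))
        table = table[~empty]
    return table


@dataclass
class EvaluationResult:
    """Threshold scan of one score column against surgical outcomes."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # fraction of good outcomes predicted good
    specificity: np.ndarray  # fraction of poor outcomes predicted poor
    balanced_accuracy: np.ndarray
    confusion: pd.DataFrame  # per-threshold TP/FN/TN/FP counts
    optimal_threshold: float
    optimal_balanced_accuracy: float
    n_good: int
    n_poor: int
    direction: str = "high score predicts good outcome"

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "balanced_accuracy": self.balanced_accuracy.tolist(),
            "optimal_threshold": self.optimal_threshold,
            "optimal_balanced_accuracy": self.optimal_balanced_accuracy,
            "n_good": self.n_good,
            "n_poor": self.n_poor,
            "direction": self.direction,
        }


def threshold_scan(
    scores: pd.Series | np.ndarray,
    outcomes,
    step: float = 0.05,
) -> EvaluationResult:
    """Scan decision thresholds over [0, 1] for good-vs-poor separation.

    ``outcomes`` are Engel classes ("I".."IV") or the strings
    "good"/"poor"; a patient is predicted good when its score >= threshold.
    """
    s = np.asarray(scores, dtype=float)
    lab = []
    for o in outcomes:
        o = str(o)
        if o in GOOD_OUTCOMES or o.lower() == "good":
            lab.append(True)
        elif o in POOR_OUTCOMES or o.lower() == "poor":
            lab.append(False)
        else:
            raise ValueError(f"unrecognized outcome {o!r}")
    good = np.asarray(lab)
    if s.size != good.size:
        raise ValueError("scores and outcomes differ in length")
    keep = np.isfinite(s)
    s, good = s[keep], good[keep]
    n_good, n_poor = int(good.sum()), int((~good).sum())
    if n_good == 0 or n_poor == 0:
        raise ValueError("both outcome groups are needed to evaluate separation")
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide [0, 1] evenly")
    grid = np.linspace(0.0, 1.0, n_steps + 1)
    sens = np.empty_like(grid)
    spec = np.empty_like(grid)
    rows = []
    for k, t in enumerate(grid):
        pred_good = s >= t
        tp = int((pred_good & good).sum())
        fn = n_good - tp
        fp = int((pred_good & ~good).sum())
        tn = n_poor - fp
        sens[k] = tp / n_good
        spec[k] = tn / n_poor
        rows.append({"threshold": t, "tp": tp, "fn": fn, "tn": tn, "fp": fp})
    bal = (sens + spec) / 2.0
    best = int(np.argmax(bal))  # argmax takes the first (smallest t) on ties
    return EvaluationResult(
        thresholds=grid,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=bal,
        confusion=pd.DataFrame(rows),
        optimal_threshold=float(grid[best]),
        optimal_balanced_accuracy=float(bal[best]),
        n_good=n_good,
        n_poor=n_poor,
    )


def overlap_analysis(
    scores: pd.DataFrame,
    roi_masks: dict[tuple[str, str], RoiMask],
    resections: dict[str, RoiMask],
    outcomes: pd.Series,
    score_cut: float = 0.9,
    overlap_cut: float = 0.8,
) -> pd.DataFrame:
    """Fraction of high-scoring regions that lie inside the resection.

    A region counts when its score exceeds ``score_cut`` and at least
    ``overlap_cut`` of its voxels fall inside the patient's resection mask.
    Reported per modality and outcome group as the percentage of counted
    regions among high-scoring regions.

    ``roi_masks`` maps ``(patient_id, roi_id)`` to the region mask;
    ``resections`` maps ``patient_id`` to the resection mask; ``outcomes``
    maps ``patient_id`` to an Engel class.
    """
    rows = []
    for col in SCORE_COLUMNS:
        if col not in scores.columns:
            continue
        for group, classes in (("good", GOOD_OUTCOMES), ("poor", POOR_OUTCOMES)):
            high = 0
            counted = 0
            for _, row in scores.iterrows():
                pid, roi = row["patient_id"], row["roi_id"]
                if str(outcomes.get(pid)) not in classes:
                    continue
                val = row[col]
                if not np.isfinite(val) or val <= score_cut:
                    continue
                if pid not in resections or (pid, roi) not in roi_masks:
                    continue
                high += 1
                frac = roi_masks[(pid, roi)].fraction_inside(resections[pid])
                if frac >= overlap_cut:
                    counted += 1
            rows.append(
                {
                    "modality": col,
                    "outcome_group": group,
                    "n_high": high,
                    "n_overlapping": counted,
                    "overlap_pct": 100.0 * counted / high if high else np.nan,
                }
            )
    return pd.DataFrame(rows)


def modality_correlation(patient_table: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation between the two modality patient scores."""
    both = patient_table[["score_ieeg", "score_fmri"]].dropna()
    if len(both) < 4:
        raise ValueError("need at least 4 patients with both modality scores")
    for c in ("score_ieeg", "score_fmri"):
        if both[c].nunique() == 1:
            raise ValueError(f"{c} is constant; rank correlation undefined")
    rho, p = stats.spearmanr(both["score_ieeg"], both["score_fmri"])
    return float(rho), float(p)
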