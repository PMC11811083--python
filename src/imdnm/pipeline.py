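"""End-to-end orchestration: score recordings and ROI series, combine the
modalities, and evaluate a cohort against surgical outcomes.

The patient-level evaluation averages region scores over the surgically
evaluated (planned) regions — region scores themselves are normalized within
the patient over *all* modeled regions, so a patient whose plan misses the
true onset region keeps low planned-region scores even though some region in
the full map always scores 1.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combine import (
    EvaluationResult,
    combine,
    modality_correlation,
    overlap_analysis,
    patient_scores,
    threshold_scan,
)
from .cohort import cohort_summary, filter_cohort, read_cohort
from .csd import CrossSpectralModel, bayesian_model_average, outbound_excitation_score
from .data import Recording, RoiSeries, read_recording, read_roi_series
from .simulate import CohortSim, simulate_cohort
from .sourcesink import SourceSinkModel

__all__ = [
    "ssi_scores_for_recording",
    "csd_scores_for_series",
    "CohortScores",
    "score_cohort",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

# Preprocessing defaults for synthetic recordings: no line noise or drift is
# simulated, so the band-pass and notch stages are skipped; the common
# average is likewise skipped because synthetic channels share no reference.
SYNTH_SSI_KW = dict(band=None, notch_band=None, car=False)


def ssi_scores_for_recording(
    rec: Recording,
    window_ms: float = 500.0,
    top_frac: float = 0.10,
    band: tuple | None = (0.5, 300.0),
    notch_band: tuple | None = (60.0, 2.0),
    car: bool = True,
):
    """Fit the source-sink model and return (channel table, ROI scores)."""
    res = SourceSinkModel(
        rec, window_ms=window_ms, top_frac=top_frac,
        band=band, notch_band=notch_band, car=car,
    ).fit()
    return res.channel_scores, res.roi_scores()


def csd_scores_for_series(
    series: RoiSeries,
    cap: int = 256,
    freqs: np.ndarray | None = None,
    mvar_order: int = 8,
):
    """Fit, reduce and average the cross-spectral model; return
    (results, bma_A, per-ROI outbound-excitation scores)."""
    res = CrossSpectralModel(series, freqs=freqs, mvar_order=mvar_order).fit()
    space = res.reduce()
    bma = bayesian_model_average(space, cap=cap)
    scores = outbound_excitation_score(bma, roi_ids=series.roi_ids)
    return res, bma, scores


@dataclass
class CohortScores:
    """Region and patient scores plus the outcome evaluation of a cohort."""

    region_scores: pd.DataFrame  # all regions, both modalities + combined
    patient_table: pd.DataFrame  # plan-restricted patient means + outcome
    evaluations: dict  # modality -> EvaluationResult
    overlap: pd.DataFrame
    correlation: tuple  # (rho, p) across patients

    def plot_outcome_separation(self, ax=None):
        """Box plots of patient scores per modality, split by outcome group.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        table = self.patient_table
        good = table["engel_class"].isin(["I", "II"])
        cols = ["score_ieeg", "score_fmri", "score_combined"]
        data, positions, labels = [], [], []
        for k, col in enumerate(cols):
            data += [table.loc[good, col].dropna(), table.loc[~good, col].dropna()]
            positions += [3 * k, 3 * k + 1]
            labels += [f"{col.split('_')[1]}\ngood", f"{col.split('_')[1]}\npoor"]
        ax.boxplot(data, positions=positions, widths=0.8)
        ax.set_xticks(positions, labels)
        ax.set_ylabel("patient-level index score")
        ax.set_title("Outcome separation by modality")
        return ax

    def report(self) -> dict:
        return {
            "evaluations": {k: v.to_dict() for k, v in self.evaluations.items()},
            "overlap": self.overlap.to_dict(orient="records"),
            "modality_correlation": {
                "rho": self.correlation[0],
                "p": self.correlation[1],
            },
            "n_patients": int(len(self.patient_table)),
        }


def score_cohort(
    sim: CohortSim,
    window_ms: float = 500.0,
    top_frac: float = 0.10,
    step: float = 0.05,
    score_cut: float = 0.9,
    overlap_cut: float = 0.8,
    restrict_to_plan: bool = True,
) -> CohortScores:
    """Run both modality pipelines over a synthetic cohort and evaluate.

    ``restrict_to_plan`` controls whether patient-level averages use only
    the surgically evaluated regions (default) or every modeled region.
    """
    rows = []
    roi_masks = {}
    resections = {}
    outcomes = {}
    for p in sim.patients:
        _, ieeg_roi = ssi_scores_for_recording(
            p.recording, window_ms=window_ms, top_frac=top_frac, **SYNTH_SSI_KW
        )
        _, _, fmri_roi = csd_scores_for_series(p.roi_series)
        for roi in p.roi_series.roi_ids:
            rows.append(
                {
                    "patient_id": p.record.id,
                    "roi_id": roi,
                    "score_ieeg": float(ieeg_roi.get(roi, np.nan)),
                    "score_fmri": float(fmri_roi.get(roi, np.nan)),
                    "in_plan": roi in p.plan_rois,
                }
            )
            roi_masks[(p.record.id, roi)] = p.roi_masks[roi]
        resections[p.record.id] = p.resection
        outcomes[p.record.id] = p.record.engel_class
    region_scores = combine(pd.DataFrame(rows))
    eval_scores = (
        region_scores[region_scores["in_plan"]] if restrict_to_plan else region_scores
    )
    patient_table = patient_scores(eval_scores)
    outcome_series = pd.Series(outcomes)
    patient_table = patient_table.join(outcome_series.rename("engel_class"))
    evaluations = {
        col: threshold_scan(patient_table[col], patient_table["engel_class"], step=step)
        for col in ("score_ieeg", "score_fmri", "score_combined")
    }
    overlap = overlap_analysis(
        region_scores, roi_masks, resections, outcome_series,
        score_cut=score_cut, overlap_cut=overlap_cut,
    )
    rho_p = modality_correlation(patient_table)
    return CohortScores(
        region_scores=region_scores,
        patient_table=patient_table,
        evaluations=evaluations,
        overlap=overlap,
        correlation=rho_p,
    )


# ---------------------------------------------------------------------------
# config-driven runs
# ---------------------------------------------------------------------------


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the stages named by a JSON config and write their outputs.

    Recognized config keys:

    * ``seed`` — master seed (default 20250128)
    * ``simulate`` — ``{"n_patients": .., "frac_good": ..}``: generate a
      synthetic cohort and run the full chain through evaluation
    * ``ieeg`` — ``{"recording": path, "sidecar": path}``: source-sink
      scores of one recording
    * ``fmri`` — ``{"series": path, "tr": seconds}``: cross-spectral scores
      of one ROI series
    * ``cohort`` — path of a cohort CSV: inclusion filtering and summary
    * tuning keys ``window_ms, top_frac, step, score_cut, overlap_cut``

    Returns the run manifest.  Outputs land in ``out_dir`` (default ``.``).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 20250128))
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    if not any(k in config for k in ("simulate", "ieeg", "fmri", "cohort")):
        raise ValueError(
            "config names no inputs: need one of 'simulate', 'ieeg', 'fmri', 'cohort'"
        )
    for key in ("ieeg", "fmri"):
        if key in config:
            for k, v in config[key].items():
                if k in ("recording", "sidecar", "series") and not Path(v).exists():
                    raise FileNotFoundError(f"{key}.{k}: no such file {v!r}")
    if "cohort" in config and not Path(config["cohort"]).exists():
        raise FileNotFoundError(f"cohort: no such file {config['cohort']!r}")

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}

        return done

    if "cohort" in config:
        end = stage("cohort-summary")
        records = read_cohort(config["cohort"])
        included, excluded = filter_cohort(records)
        summary = cohort_summary(included)
        summary["excluded"] = excluded
        with open(out / "cohort_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        end()

    if "simulate" in config:
        end = stage("simulate+evaluate")
        sim = simulate_cohort(
            n_patients=int(config["simulate"].get("n_patients", 17)),
            frac_good=float(config["simulate"].get("frac_good", 12 / 17)),
            seed=seed,
        )
        scored = score_cohort(
            sim,
            window_ms=float(config.get("window_ms", 500.0)),
            top_frac=float(config.get("top_frac", 0.10)),
            step=float(config.get("step", 0.05)),
            score_cut=float(config.get("score_cut", 0.9)),
            overlap_cut=float(config.get("overlap_cut", 0.8)),
        )
        scored.region_scores.to_csv(out / "region_scores.csv", index=False)
        scored.patient_table.to_csv(out / "patient_scores.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(scored.report(), fh, indent=1)
        end()

    if "ieeg" in config:
        end = stage("ssi")
        rec = read_recording(
            config["ieeg"]["recording"], config["ieeg"].get("sidecar")
        )
        kw = {}
        if config["ieeg"].get("synthetic", False):
            kw = SYNTH_SSI_KW
        channels, rois = ssi_scores_for_recording(
            rec,
            window_ms=float(config.get("window_ms", 500.0)),
            top_frac=float(config.get("top_frac", 0.10)),
            **kw,
        )
        channels.to_csv(out / "ssi_channels.csv")
        rois.to_frame().to_csv(out / "ssi_rois.csv")
        end()

    if "fmri" in config:
        end = stage("csd")
        series = read_roi_series(
            config["fmri"]["series"], tr=float(config["fmri"].get("tr", 2.0))
        )
        _, bma, scores = csd_scores_for_series(series)
        pd.DataFrame(bma, index=series.roi_ids, columns=series.roi_ids).to_csv(
            out / "csd_bma_A.csv"
        )
        scores.to_frame().to_csv(out / "csd_scores.csv")
        end()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
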