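"""End-to-end phantom studies: simulate -> register -> segment -> measure ->
SULTAN -> classify -> evaluate.

`process_cohort` turns a phantom cohort into per-lesion measurements;
`run_per_lesion_study` / `run_per_patient_study` aggregate them into
diagnostic reports (one row per metric plus a SULTAN row per analysis level).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import phantom as ph
from .evaluation import RocResult, confusion_stats, roc
from .metrics import METRIC_NAMES, compute_all
from .registration import BlockMatchConfig, register_rigid, resample_through
from .response import (
    NON_RESPONDER,
    RESPONDER,
    ResponsePair,
    ThresholdPolicy,
    confusion_cell,
    patient_change_percist,
    percent_change,
    select_targets,
)
from .segmentation import SegmentationConfig, SegmentationError, segment_lesion
from .sultan import (
    FadsConfig,
    TwoFrameFactorAnalysis,
    classify_lesion_sultan,
    classify_patient_sultan,
)

__all__ = ["RunConfig", "StudyReport", "CohortMeasurements", "process_cohort",
           "run_per_lesion_study", "run_per_patient_study"]


@dataclass
class RunConfig:
    """Configuration of a full phantom study (validated up front, serialized
    into the output directory for provenance)."""

    n_patients: int = 40
    seed: int = 0
    grid_shape: tuple = (96, 96, 96)
    spacing: tuple = (2.0, 2.0, 2.0)
    response_mix: dict | None = None
    psf_fwhm: float = 6.0
    noise_sigma: float = 0.15
    misalign: bool = True
    register: bool = True
    registration: BlockMatchConfig = field(default_factory=BlockMatchConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    fads: FadsConfig = field(default_factory=FadsConfig)
    sultan_threshold: float = 1.0
    sam_margin_mm: float = 8.0
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.misalign and not self.register:
            raise ValueError("misaligned cohorts require registration")
        if self.sultan_threshold < 0:
            raise ValueError("sultan_threshold must be non-negative")

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, indent=2)


@dataclass
class CohortMeasurements:
    """Everything measured on a cohort, before any thresholding."""

    evolutions: pd.DataFrame      # one row per lesion evolution
    pairs: list                   # list[ResponsePair]
    patient_gold: dict            # pair_id -> gold label
    sultan_patient: dict          # pair_id -> SULTAN label
    dropped: list                 # lesions whose baseline was non-measurable


@dataclass
class StudyReport:
    level: str                    # "lesion" | "patient"
    table: pd.DataFrame
    rocs: dict                    # metric -> RocResult
    measurements: CohortMeasurements

    def summary(self) -> str:
        cols = [c for c in self.table.columns if c != "chi2_p"]
        return (
            f"Per-{self.level} diagnostic evaluation "
            f"(n = {self.table['n'].iloc[0]})\n" + self.table[cols].to_string(index=False)
        )


def _measure_pair(baseline, followup, truth, spec_lesions, cfg: RunConfig,
                  pair_id, patient_id):
    """Register, segment and measure every lesion of one phantom pair."""
    if cfg.register and cfg.misalign:
        transform = register_rigid(baseline, followup, cfg.registration)
        aligned = resample_through(followup, transform, baseline)
    else:
        transform, aligned = None, followup
    roi = None
    if aligned.validity is not None:
        roi = ndimage.binary_erosion(aligned.validity, iterations=2)
    fads = TwoFrameFactorAnalysis(baseline, aligned, roi=roi, config=cfg.fads).fit()
    simage = fads.sultan_image(cfg.sultan_threshold)

    lesion_rows, base_metrics, follow_metrics, dropped = [], [], [], []
    for _, lesion in truth.lesions.iterrows():
        lesion_id = lesion["lesion_id"]
        spec_lesion = next(l for l in spec_lesions if l.lesion_id == lesion_id)
        seed = tuple(
            int(round(c / s)) for c, s in zip(spec_lesion.center, cfg.spacing)
        )
        try:
            voi = segment_lesion(
                baseline, seed, cfg.segmentation, lesion_id=lesion_id,
                organ=lesion["organ"],
            )
        except SegmentationError as err:
            dropped.append((pair_id, lesion_id, str(err)))
            continue
        fallback = False
        try:
            voi2 = segment_lesion(
                aligned, seed, cfg.segmentation, lesion_id=lesion_id,
                organ=lesion["organ"],
            )
        except SegmentationError:
            # resolved lesion: residual uptake measured through the baseline
            # mask transferred onto the registered follow-up
            voi2, fallback = voi, True
        m1 = compute_all(baseline, voi, sam_margin_mm=cfg.sam_margin_mm)
        m2 = compute_all(aligned, voi2, sam_margin_mm=cfg.sam_margin_mm)
        sultan_label = classify_lesion_sultan(simage, voi)
        row = {
            "patient_id": patient_id,
            "pair_id": pair_id,
            "lesion_id": lesion_id,
            "organ": lesion["organ"],
            "gold_label": lesion["gold_label"],
            "true_change_pct": lesion["true_change_pct"],
            "sultan_label": sultan_label,
            "followup_fallback": fallback,
        }
        for metric in METRIC_NAMES:
            row[f"{metric}_t1"] = m1.value(metric)
            row[f"{metric}_t2"] = m2.value(metric)
            row[f"{metric}_change_pct"] = (
                percent_change(m1.value(metric), m2.value(metric))
                if m1.value(metric) > 0
                else np.nan
            )
        lesion_rows.append(row)
        base_metrics.append(m1)
        follow_metrics.append(m2)
    return lesion_rows, base_metrics, follow_metrics, dropped, transform


def process_cohort(cfg: RunConfig, cohort: ph.Cohort | None = None) -> CohortMeasurements:
    """Measure a whole cohort (generated from ``cfg`` unless provided)."""
    if cohort is None:
        cohort = ph.generate_cohort(
            cfg.n_patients,
            response_mix=cfg.response_mix,
            seed=cfg.seed,
            grid_shape=cfg.grid_shape,
            spacing=cfg.spacing,
            misalign=cfg.misalign,
            psf_fwhm=cfg.psf_fwhm,
            noise_sigma=cfg.noise_sigma,
        )
    rows, pairs, patient_gold, sultan_patient, dropped = [], [], {}, {}, []
    for (pid, pair_id, baseline, followup, truth), spec in zip(
        cohort.pairs(), cohort.specs
    ):
        lesion_rows, m1s, m2s, drop, _ = _measure_pair(
            baseline, followup, truth, spec.lesions, cfg, pair_id, pid
        )
        rows.extend(lesion_rows)
        dropped.extend(drop)
        if not m1s:
            continue
        targets = select_targets(m1s)
        target_ids = {m.lesion_id for m in targets}
        pairs.append(
            ResponsePair(
                pair_id=pair_id,
                patient_id=pid,
                baseline=[m for m in m1s if m.lesion_id in target_ids],
                followup=[m for m in m2s if m.lesion_id in target_ids],
                gold_label=truth.patient_label,
            )
        )
        patient_gold[pair_id] = truth.patient_label
        sultan_patient[pair_id] = classify_patient_sultan(
            [r["sultan_label"] for r in lesion_rows]
        )
    measurements = CohortMeasurements(
        evolutions=pd.DataFrame(rows),
        pairs=pairs,
        patient_gold=patient_gold,
        sultan_patient=sultan_patient,
        dropped=dropped,
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.json").write_text(cfg.to_json())
        measurements.evolutions.to_csv(out / "evolutions.csv", index=False)
        cohort.lesion_catalog.to_csv(out / "lesion_catalog.csv", index=False)
        cohort.gold_standard.to_csv(out / "gold_standard.csv", index=False)
    return measurements


def _stats_row(metric, source, threshold, auc, counts, n):
    tp, tn, fp, fn = counts
    stats = confusion_stats(tp, tn, fp, fn)
    row = {
        "metric": metric,
        "threshold_source": source,
        "threshold_pct": threshold,
        "auc": auc,
        "n": n,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }
    row.update(stats.as_percent_row())
    return row


def _call(change, cut):
    """Responder call at a raw ROC cut (which, unlike a policy threshold, may
    be zero or negative for uninformative metrics)."""
    return RESPONDER if change < -cut else NON_RESPONDER


def _counts(calls, gold_labels):
    cells = [confusion_cell(c, g) for c, g in zip(calls, gold_labels)]
    return (cells.count("TP"), cells.count("TN"), cells.count("FP"), cells.count("FN"))


def run_per_lesion_study(
    cfg: RunConfig, measurements: CohortMeasurements | None = None
) -> StudyReport:
    """Per-lesion evaluation: for each metric, percent changes -> ROC ->
    Youden-optimal threshold -> confusion statistics; plus the SULTAN row."""
    meas = measurements if measurements is not None else process_cohort(cfg)
    df = meas.evolutions
    if df.empty or df["gold_label"].nunique() < 2:
        raise ValueError("per-lesion study needs both gold classes")
    gold = df["gold_label"].tolist()
    rows, rocs = [], {}
    for metric in METRIC_NAMES:
        changes = df[f"{metric}_change_pct"].to_numpy()
        ok = np.isfinite(changes)
        r = roc(changes[ok], np.asarray(gold)[ok])
        rocs[metric] = r
        calls = [_call(c, r.optimal_threshold) for c in changes[ok]]
        rows.append(
            _stats_row(
                metric, "optimal", r.optimal_threshold, r.auc,
                _counts(calls, np.asarray(gold)[ok]), int(ok.sum()),
            )
        )
    rows.append(
        _stats_row(
            "sultan", "sultan", np.nan, np.nan,
            _counts(df["sultan_label"].tolist(), gold), len(df),
        )
    )
    report = StudyReport("lesion", pd.DataFrame(rows), rocs, meas)
    _maybe_write(cfg, report, "per_lesion_report.csv")
    return report


def run_per_patient_study(
    cfg: RunConfig,
    measurements: CohortMeasurements | None = None,
    optimal_policy: ThresholdPolicy | None = None,
) -> StudyReport:
    """Per-patient evaluation under the PERCIST policy and the cohort-optimal
    thresholds (hottest-lesion percent change), plus the SULTAN patient rule."""
    meas = measurements if measurements is not None else process_cohort(cfg)
    if not meas.pairs:
        raise ValueError("no evaluable pairs")
    gold = [p.gold_label for p in meas.pairs]
    if len(set(gold)) < 2:
        raise ValueError("per-patient study needs both gold classes")
    percist = ThresholdPolicy.percist()
    rows, rocs = [], {}
    for metric in METRIC_NAMES:
        changes = np.array([patient_change_percist(p, metric) for p in meas.pairs])
        r = roc(changes, gold)
        rocs[metric] = r
        if optimal_policy is not None:
            opt_thr = optimal_policy.threshold(metric)
        else:
            opt_thr = r.optimal_threshold
        for source, thr in (("percist", percist.threshold(metric)), ("optimal", opt_thr)):
            calls = [_call(c, thr) for c in changes]
            rows.append(_stats_row(metric, source, thr, r.auc, _counts(calls, gold), len(gold)))
    sultan_calls = [meas.sultan_patient[p.pair_id] for p in meas.pairs]
    rows.append(
        _stats_row("sultan", "sultan", np.nan, np.nan, _counts(sultan_calls, gold), len(gold))
    )
    report = StudyReport("patient", pd.DataFrame(rows), rocs, meas)
    _maybe_write(cfg, report, "per_patient_report.csv")
    return report


def _maybe_write(cfg: RunConfig, report: StudyReport, name: str):
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.table.to_csv(out / name, index=False)
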