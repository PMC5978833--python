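"""Trial and cohort reporting: per-trial summary rows, group mean ± SD
statistics, repeatability (coefficient of variation), and group
comparisons.

Conventions: cohort statistics use the sample standard deviation
(n - 1 denominator); subjects with repeat trials enter group statistics
through their per-subject mean; human-readable reports round areas,
angles and EMG percentages to integers (half-to-even) while the
machine-readable JSON keeps full precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .envelope import cv_across_trials
from .errors import ReachmapError
from .pipeline import TrialAnalysis

SCHEMA_VERSION = "1"

#: Metric keys of a trial row, in report column order.
METRICS = (
    "surface_area_deg2",
    "max_flexion",
    "max_abduction",
    "max_extension",
    "max_horizontal_abduction",
    "emg_ant_pct_mvc",
    "emg_mid_pct_mvc",
    "emg_post_pct_mvc",
)


@dataclass
class TrialResult:
    """One analyzed trial, flattened to report metrics; None = NA."""

    subject: str
    trial: int
    surface_area_deg2: float
    area_mode: str
    max_flexion: Optional[float]
    max_abduction: Optional[float]
    max_extension: Optional[float]
    max_horizontal_abduction: Optional[float]
    region_sample_counts: Dict[str, int]
    emg_channel_means: Dict[str, float]
    emg_region_means: Optional[Dict[str, dict]] = None

    def metrics(self) -> Dict[str, Optional[float]]:
        out: Dict[str, Optional[float]] = {
            "surface_area_deg2": self.surface_area_deg2,
            "max_flexion": self.max_flexion,
            "max_abduction": self.max_abduction,
            "max_extension": self.max_extension,
            "max_horizontal_abduction": self.max_horizontal_abduction,
        }
        for short, key in (
            ("emg_ant", "emg_ant_pct_mvc"),
            ("emg_mid", "emg_mid_pct_mvc"),
            ("emg_post", "emg_post_pct_mvc"),
        ):
            out[key] = self.emg_channel_means.get(short)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"schema_version": SCHEMA_VERSION, **asdict(self)}, indent=2, sort_keys=True
        )


def summarize_trial(
    analysis: TrialAnalysis, subject: str = "s1", trial: int = 1
) -> TrialResult:
    """Assemble the report row for one analyzed stream."""
    if analysis.envelope is None or not analysis.envelope.visited.any():
        raise ReachmapError("trial has no envelope; nothing to summarize")
    m = analysis.maxima
    return TrialResult(
        subject=subject,
        trial=trial,
        surface_area_deg2=analysis.surface_area_deg2,
        area_mode=analysis.area_mode,
        max_flexion=m.max_flexion,
        max_abduction=m.max_abduction,
        max_extension=m.max_extension,
        max_horizontal_abduction=m.max_horizontal_abduction,
        region_sample_counts=analysis.region_sample_counts,
        emg_channel_means=analysis.emg_channel_means,
        emg_region_means=analysis.emg_region_summary,
    )


@dataclass
class CohortSummary:
    """Per-group mean and sample SD of each metric, plus repeatability.

    ``per_metric``: {metric: {"mean", "sd", "n"}} over subjects (each
    subject reduced to the mean of its repeat trials first; NA metrics
    are excluded pairwise).  ``per_subject_cv``: coefficient of
    variation (%) of surface area across each subject's repeats, where
    a subject has >= 2 repeats.
    """

    group: str
    n_subjects: int
    per_metric: Dict[str, dict]
    per_subject_cv: Dict[str, float]


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            if isinstance(rec, TrialResult):
                rows.append({"subject": rec.subject, "trial": rec.trial, **rec.metrics()})
            elif isinstance(rec, Mapping):
                rows.append(dict(rec))
            else:
                raise ReachmapError(f"unsupported record type {type(rec)!r}")
        df = pd.DataFrame(rows)
    if "subject" not in df.columns:
        raise ReachmapError("records need a 'subject' column")
    return df


def summarize_cohort(records, group: str = "healthy") -> CohortSummary:
    """Cohort statistics across subjects for one group.

    ``records`` is a DataFrame or a sequence of :class:`TrialResult` /
    dicts with a ``subject`` column plus metric columns.  Repeat trials
    are averaged per subject before group mean and sample SD (n - 1);
    a single-subject group gets SD 0 by convention, with a warning.
    """
    df = _records_frame(records)
    if df.empty:
        raise ReachmapError("empty group")
    metric_cols = [c for c in METRICS if c in df.columns]
    if not metric_cols:
        raise ReachmapError("no metric columns found")

    per_subject_cv: Dict[str, float] = {}
    if "surface_area_deg2" in df.columns:
        for subject, grp in df.groupby("subject"):
            areas = grp["surface_area_deg2"].dropna()
            if len(areas) >= 2:
                per_subject_cv[str(subject)] = cv_across_trials(areas.to_numpy())

    subject_means = df.groupby("subject")[metric_cols].mean()
    n_subjects = len(subject_means)
    per_metric: Dict[str, dict] = {}
    for col in metric_cols:
        vals = subject_means[col].dropna().to_numpy(float)
        if len(vals) == 0:
            per_metric[col] = {"mean": None, "sd": None, "n": 0}
            continue
        if len(vals) == 1:
            warnings.warn(
                f"group {group!r}: single subject for {col}; SD set to 0 by convention",
                stacklevel=2,
            )
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        per_metric[col] = {"mean": float(np.mean(vals)), "sd": sd, "n": int(len(vals))}
    return CohortSummary(
        group=group,
        n_subjects=n_subjects,
        per_metric=per_metric,
        per_subject_cv=per_subject_cv,
    )


def compare_groups(a: CohortSummary, b: CohortSummary) -> pd.DataFrame:
    """Per-metric difference (b - a) and ratio (100 * b / a, percent of
    the reference group ``a``).  No inferential statistics are attached.
    """
    metrics_a = {k for k, v in a.per_metric.items() if v["mean"] is not None}
    metrics_b = {k for k, v in b.per_metric.items() if v["mean"] is not None}
    common = [m for m in METRICS if m in (metrics_a & metrics_b)]
    if metrics_a != metrics_b:
        missing = sorted(metrics_a ^ metrics_b)
        raise ReachmapError(f"groups report different metrics: {missing}")
    rows = []
    for m in common:
        ma, mb = a.per_metric[m]["mean"], b.per_metric[m]["mean"]
        rows.append(
            {
                "metric": m,
                f"{a.group}_mean": ma,
                f"{b.group}_mean": mb,
                "difference": mb - ma,
                "ratio_pct": 100.0 * mb / ma if ma != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def round_report(value: Optional[float]) -> Optional[int]:
    """Integer rounding used in human-readable tables (half-to-even)."""
    return None if value is None else int(np.rint(value))


def cohort_table(summary: CohortSummary) -> pd.DataFrame:
    """Human-readable mean ± SD table with report rounding applied."""
    rows = []
    for metric in METRICS:
        stats = summary.per_metric.get(metric)
        if stats is None or stats["mean"] is None:
            continue
        rows.append(
            {
                "metric": metric,
                "mean": round_report(stats["mean"]),
                "sd": round_report(stats["sd"]),
                "n": stats["n"],
            }
        )
    return pd.DataFrame(rows)


def cohort_to_json(summaries: Sequence[CohortSummary]) -> str:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "groups": [asdict(s) for s in summaries],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
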