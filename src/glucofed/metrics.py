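"""Glycemic outcome statistics: five-range time percentages, cohort tables, risk trajectories.

Range boundaries follow the consensus CGM reporting bands with 70 and 180
inclusive in the target range:

    [0, 50)  [50, 70)  [70, 180]  (180, 250]  (250, inf)
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .reward import bg_risk

RANGE_LABELS = ("pct_below_50", "pct_50_70", "pct_70_180", "pct_180_250", "pct_above_250")
RANGE_HEADERS = ("<50 mg/dL, %", "50-70 mg/dL, %", "70-180 mg/dL, %",
                 "180-250 mg/dL, %", ">250 mg/dL, %")
COHORT_ORDER = ("child", "adolescent", "adult", "overall")


@dataclass(frozen=True)
class GlycemicReport:
    pct_below_50: float
    pct_50_70: float
    pct_70_180: float
    pct_180_250: float
    pct_above_250: float
    n_samples: int

    @property
    def tir(self) -> float:
        """Time in range 70-180 mg/dL, %."""
        return self.pct_70_180

    def percentages(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in RANGE_LABELS])

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _glucose_series(trace, use_cgm: bool) -> np.ndarray:
    if hasattr(trace, "cgm"):
        values = trace.cgm if use_cgm else trace.plasma_glucose
    else:  # bare array-like of glucose values
        values = trace
    return np.asarray(values, dtype=float)


def classify_range(glucose) -> np.ndarray:
    """Index (0..4) of the unique range bin for each positive glucose value."""
    g = np.asarray(glucose, dtype=float)
    if np.any(g <= 0):
        raise ValidationError("glucose values must be positive")
    idx = np.full(g.shape, 2, dtype=int)       # [70, 180]
    idx[g < 70.0] = 1                          # [50, 70)
    idx[g < 50.0] = 0                          # [0, 50)
    idx[g > 180.0] = 3                         # (180, 250]
    idx[g > 250.0] = 4                         # (250, inf)
    return idx


def glycemic_report(trace, use_cgm: bool = False) -> GlycemicReport:
    """Percent of samples in each of the five glucose ranges.

    ``trace`` may be an EpisodeTrace or any array of glucose values.
    ``use_cgm`` selects the sensor series instead of plasma glucose.
    """
    g = _glucose_series(trace, use_cgm)
    if g.size == 0:
        raise ValidationError("trace is empty")
    counts = np.bincount(classify_range(g), minlength=5)
    pct = 100.0 * counts / g.size
    return GlycemicReport(*map(float, pct), n_samples=int(g.size))


def cohort_aggregate(reports: list[GlycemicReport], labels: list[str]) -> dict[str, GlycemicReport]:
    """Unweighted per-cohort means of the range percentages, plus 'overall'.

    Output keys are ordered child / adolescent / adult / overall, restricted
    to cohorts present in ``labels``.
    """
    if not reports:
        raise ValidationError("need at least one report")
    if len(reports) != len(labels):
        raise ValidationError("reports and labels must have equal length")
    known = set(COHORT_ORDER[:3])
    for lab in labels:
        if lab not in known:
            raise ValidationError(f"unknown cohort label {lab!r}")

    def mean_of(subset: list[GlycemicReport]) -> GlycemicReport:
        mat = np.stack([r.percentages() for r in subset])
        return GlycemicReport(*map(float, mat.mean(axis=0)),
                              n_samples=int(sum(r.n_samples for r in subset)))

    out: dict[str, GlycemicReport] = {}
    for cohort in COHORT_ORDER[:3]:
        subset = [r for r, lab in zip(reports, labels) if lab == cohort]
        if subset:
            out[cohort] = mean_of(subset)
    out["overall"] = mean_of(list(reports))
    return out


def risk_trajectory(trace, window: int, use_cgm: bool = False) -> pd.Series:
    """Rolling mean of the blood-glucose risk score along a trace.

    Returns a series of the same length as the trace, indexed by time
    (minutes) when available; leading entries use expanding partial windows.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    g = _glucose_series(trace, use_cgm)
    if window > g.size:
        raise ValidationError("window exceeds trace length")
    risk = bg_risk(g)
    rolled = pd.Series(risk).rolling(window, min_periods=1).mean()
    index = np.asarray(trace.t_min) if hasattr(trace, "t_min") else np.arange(g.size)
    return pd.Series(rolled.to_numpy(), index=index, name="mean_bg_risk")


def render_table(summary: dict[str, GlycemicReport]) -> dict[str, object]:
    """Render a cohort summary as aligned text, CSV, and a JSON-ready dict."""
    rows = [(k, summary[k]) for k in COHORT_ORDER if k in summary]
    frame = pd.DataFrame(
        [[round(v, 2) for v in rep.percentages()] for _, rep in rows],
        index=[name.capitalize() for name, _ in rows],
        columns=RANGE_HEADERS,
    )
    frame.index.name = "Patient group"
    text = frame.to_string(float_format=lambda v: f"{v:.2f}")
    buf = io.StringIO()
    frame.to_csv(buf, float_format="%.2f")
    as_json = {
        name: {lab: round(float(v), 2) for lab, v in zip(RANGE_LABELS, rep.percentages())}
        for name, rep in rows
    }
    return {"text": text, "csv": buf.getvalue(), "json": as_json,
            "json_str": json.dumps(as_json, indent=2)}
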