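"""Hit-calling rules for reporter screens.

Two k-sigma rules against control statistics, matching how positives are
scored in induction assays ("signal two standard deviations above
non-induced controls"):

* **threshold rule** — a subject is POSITIVE when its statistic strictly
  exceeds control mean + k * control sd (or falls strictly below
  mean - k * sd for loss-of-signal screens);
* **slope rule** — the statistic is the ordinary-least-squares slope of
  corrected percentage vs time, thresholded the same way against the
  control slopes.

Ties at exactly the k-sigma boundary are NEGATIVE (strict inequality —
deterministic and conservative).  A dose-trend analysis compares each
dose group against the dose-0 control and flags monotone ordering of the
group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import SubjectTimeCourse
from .plate_io import ValidationError

__all__ = [
    "HitTable",
    "ols_slope",
    "call_hits_threshold",
    "call_hits_slope",
    "dose_trend",
    "ABOVE",
    "BELOW",
]

ABOVE = "ABOVE"
BELOW = "BELOW"

HIT_COLUMNS = [
    "subject_id",
    "rule",
    "statistic",
    "control_mean",
    "control_sd",
    "k",
    "direction",
    "call",
]


@dataclass
class HitTable:
    """Deterministic per-subject hit calls; identical inputs give
    byte-identical TSV serializations."""

    rows: pd.DataFrame
    warnings: tuple[str, ...] = ()

    @property
    def positives(self) -> list[str]:
        return self.rows.loc[self.rows["call"] == "POSITIVE", "subject_id"].tolist()

    @property
    def n_positive(self) -> int:
        return int((self.rows["call"] == "POSITIVE").sum())

    def to_tsv(self, path) -> None:
        df = self.rows.copy()
        for col in ("statistic", "control_mean", "control_sd", "k"):
            df[col] = df[col].map(lambda v: repr(float(v)))
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def ols_slope(times: Sequence[float], values: Sequence[float]) -> float:
    """Least-squares slope of values vs time (exact Δ/Δt for two points)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValidationError("slope needs >= 2 points")
    if t.size == 2:
        return float((y[1] - y[0]) / (t[1] - t[0]))
    tc = t - t.mean()
    return float((tc * (y - y.mean())).sum() / (tc * tc).sum())


def _call(value: float, mean: float, sd: float, k: float, direction: str) -> str:
    if direction == ABOVE:
        return "POSITIVE" if value > mean + k * sd else "NEGATIVE"
    if direction == BELOW:
        return "POSITIVE" if value < mean - k * sd else "NEGATIVE"
    raise ValidationError(f"direction must be ABOVE or BELOW, got {direction!r}")


def call_hits_threshold(
    values: Mapping[str, float],
    controls: Sequence[float],
    k: float = 2.0,
    direction: str = ABOVE,
    rule: str = "THRESHOLD_K_SD",
) -> HitTable:
    """k-sigma threshold rule on an arbitrary per-subject statistic."""
    ctrl = np.asarray(list(controls), dtype=float)
    if ctrl.size < 2:
        raise ValidationError("need >= 2 control subjects")
    mean, sd = float(ctrl.mean()), float(ctrl.std(ddof=1))
    warnings: tuple[str, ...] = ()
    if sd == 0:
        warnings = (
            "control sd is 0: any difference from the control mean is a hit",
        )
    rows = [
        {
            "subject_id": sid,
            "rule": rule,
            "statistic": float(v),
            "control_mean": mean,
            "control_sd": sd,
            "k": float(k),
            "direction": direction,
            "call": _call(float(v), mean, sd, k, direction),
        }
        for sid, v in values.items()
    ]
    df = pd.DataFrame(rows, columns=HIT_COLUMNS).sort_values("subject_id", kind="stable")
    return HitTable(rows=df.reset_index(drop=True), warnings=warnings)


def call_hits_slope(
    timecourses: Sequence[SubjectTimeCourse],
    controls: Sequence[SubjectTimeCourse],
    k: float = 2.0,
    direction: str = ABOVE,
    corrected: bool = True,
) -> HitTable:
    """k-sigma rule on per-subject percentage-vs-time slopes."""

    def _slope(tc: SubjectTimeCourse) -> float:
        pts = [
            (p.timepoint_hpf, p.corrected_pct if corrected else p.normalized_pct)
            for p in tc.points
            if (p.corrected_pct if corrected else p.normalized_pct) is not None
        ]
        if len(pts) < 2:
            raise ValidationError(
                f"subject {tc.subject_id}: slope needs >= 2 usable timepoints"
            )
        return ols_slope([t for t, _ in pts], [v for _, v in pts])

    control_slopes = [_slope(tc) for tc in controls]
    values = {tc.subject_id: _slope(tc) for tc in timecourses}
    return call_hits_threshold(
        values, control_slopes, k=k, direction=direction, rule="SLOPE_K_SD"
    )


def dose_trend(
    groups: Mapping[float, Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
    decreasing: bool = True,
) -> dict:
    """Per-dose comparisons against the dose-0 control plus monotonicity.

    Each dose group is compared to the control with a two-sample Welch
    t-test; singleton groups are skipped with a flag.  The monotone flag
    is True iff group means (control first) are nonincreasing
    (``decreasing=True``) or nondecreasing in dose, ties allowed.
    """
    ctrl = np.asarray(list(control), dtype=float)
    if len(groups) < 2:
        raise ValidationError("need >= 2 dose groups plus control")
    comparisons = {}
    means = [float(ctrl.mean())]
    for dose in sorted(groups):
        vals = np.asarray(list(groups[dose]), dtype=float)
        means.append(float(vals.mean()) if vals.size else math.nan)
        if vals.size < 2 or ctrl.size < 2:
            comparisons[dose] = {
                "p_value": None,
                "significant": None,
                "flags": ("SINGLETON",),
            }
            continue
        _, p = stats.ttest_ind(vals, ctrl, equal_var=False)
        comparisons[dose] = {
            "p_value": float(p),
            "significant": bool(p <= alpha),
            "flags": (),
        }
    diffs = np.diff(means)
    monotone = bool(np.all(diffs <= 0)) if decreasing else bool(np.all(diffs >= 0))
    return {
        "comparisons": comparisons,
        "group_means": means,
        "monotone": monotone,
        "alpha": alpha,
    }
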