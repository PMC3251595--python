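"""Per-subject baseline normalization and untreated-control correction.

Reporter expression varies up to an order of magnitude between sibling
transgenic fish, so raw fluorescence cannot be compared across subjects.
Instead each subject serves as its own reference: the initial
(pre-treatment) scan is set to 100 % and every later scan is expressed as
a percentage of it.  A multiplicative correction factor derived from
untreated transgenic controls then removes non-induced drift in expression
or detection over time (plate, dye, instrument), so that the controls' own
corrected mean is exactly 100 % at every timepoint.

For comparisons against *non-transgenic* animals, absolute RFU summaries
are reported instead (:func:`relative_fluorescence`) since there the raw
signal difference is the quantity of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .plate_io import ValidationError

__all__ = [
    "TimeCoursePoint",
    "SubjectTimeCourse",
    "baseline_normalize",
    "control_correct",
    "control_correct_timecourses",
    "relative_fluorescence",
    "BELOW_DETECTION_BASELINE",
    "FALLBACK_USED",
    "EXCLUDED",
    "NO_CONTROLS",
]

BELOW_DETECTION_BASELINE = "BELOW_DETECTION_BASELINE"
FALLBACK_USED = "FALLBACK_USED"
EXCLUDED = "EXCLUDED"
NO_CONTROLS = "NO_CONTROLS"

_ALLOWED_FLAGS = {BELOW_DETECTION_BASELINE, FALLBACK_USED, EXCLUDED, NO_CONTROLS}


@dataclass
class TimeCoursePoint:
    session_id: str
    timepoint_hpf: float
    total_signal: float
    n_signal_regions: int = 0
    method: str = "DIRECT"
    normalized_pct: float | None = None
    corrected_pct: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.flags) - _ALLOWED_FLAGS
        if bad:
            raise ValidationError(f"unknown flags: {sorted(bad)}")


@dataclass
class SubjectTimeCourse:
    """One subject's Total-Signal trajectory and normalized percentages."""

    subject_id: str
    group: str
    channel: str
    condition: str | None = None
    points: list[TimeCoursePoint] = field(default_factory=list)

    def validate(self) -> None:
        times = [p.timepoint_hpf for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"subject {self.subject_id}: timepoints must be strictly increasing"
            )

    @property
    def excluded(self) -> bool:
        return any(EXCLUDED in p.flags for p in self.points)

    def pct_at(self, timepoint_hpf: float, corrected: bool = True) -> float | None:
        for p in self.points:
            if math.isclose(p.timepoint_hpf, timepoint_hpf):
                return p.corrected_pct if corrected else p.normalized_pct
        raise KeyError(f"no point at {timepoint_hpf} hpf for {self.subject_id}")


def baseline_normalize(timecourse: SubjectTimeCourse, baseline_session: str | None = None) -> SubjectTimeCourse:
    """Normalize a subject's trajectory to its own baseline scan.

    The baseline is the first point by time, or the named pre-treatment
    session if given.  ``normalized_pct = 100 * TS(t) / TS(baseline)``; the
    baseline point itself is exactly 100.  A zero baseline cannot anchor
    percentages: every point is flagged BELOW_DETECTION_BASELINE and
    EXCLUDED (kept in the output, excluded from group statistics), with
    percentages reported as missing.
    """
    if not timecourse.points:
        raise ValidationError(f"subject {timecourse.subject_id}: no points")
    timecourse.points.sort(key=lambda p: p.timepoint_hpf)
    timecourse.validate()
    if baseline_session is None:
        base = timecourse.points[0]
    else:
        matches = [p for p in timecourse.points if p.session_id == baseline_session]
        if not matches:
            raise ValidationError(
                f"subject {timecourse.subject_id}: no session {baseline_session!r}"
            )
        base = matches[0]
    if base.total_signal == 0:
        for p in timecourse.points:
            p.normalized_pct = None
            p.corrected_pct = None
            p.flags = tuple(
                dict.fromkeys(p.flags + (BELOW_DETECTION_BASELINE, EXCLUDED))
            )
        return timecourse
    for p in timecourse.points:
        p.normalized_pct = 100.0 * p.total_signal / base.total_signal
        if p.method != "DIRECT":
            p.flags = tuple(dict.fromkeys(p.flags + (FALLBACK_USED,)))
    base.normalized_pct = 100.0  # exact by definition, no float division residue
    return timecourse


def control_correct(
    treated_pct: Sequence[float] | np.ndarray,
    control_pcts: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Apply the untreated-control correction factor at one timepoint.

    ``corrected = 100 * treated_pct / mean(control_pcts)`` — a
    multiplicative correction, so the controls' own corrected mean is 100
    by construction and shared drift cancels exactly.
    """
    controls = np.asarray(control_pcts, dtype=float)
    if controls.size < 2:
        raise ValidationError("control correction needs >= 2 control subjects")
    m = controls.mean()
    if m == 0:
        raise ValidationError("mean control percentage is zero")
    return 100.0 * np.asarray(treated_pct, dtype=float) / m


def control_correct_timecourses(
    timecourses: Sequence[SubjectTimeCourse],
    control_group: str = "TRANSGENIC_CONTROL",
) -> list[SubjectTimeCourse]:
    """Correct all time courses against the untreated-control mean per
    (channel, timepoint).

    Excluded subjects never contribute to the control mean.  Timepoints
    with no usable controls fall back to the uncorrected percentage and
    are flagged NO_CONTROLS.
    """
    by_key: dict[tuple[str, float], list[float]] = {}
    for tc in timecourses:
        if tc.group != control_group or tc.excluded:
            continue
        for p in tc.points:
            if p.normalized_pct is not None:
                by_key.setdefault((tc.channel, p.timepoint_hpf), []).append(
                    p.normalized_pct
                )
    for tc in timecourses:
        for p in tc.points:
            if p.normalized_pct is None:
                p.corrected_pct = None
                continue
            controls = by_key.get((tc.channel, p.timepoint_hpf), [])
            if len(controls) < 2:
                p.corrected_pct = p.normalized_pct
                p.flags = tuple(dict.fromkeys(p.flags + (NO_CONTROLS,)))
            else:
                p.corrected_pct = float(
                    control_correct([p.normalized_pct], controls)[0]
                )
    return list(timecourses)


def corrected_group_mean(
    treated_corrected: Sequence[float] | np.ndarray,
    controls_corrected: Sequence[float] | np.ndarray,
) -> dict:
    """Mean and standard error of a corrected group mean.

    Corrected percentages share the control-correction factor, so they are
    not independent: the naive across-fish sem omits the (common)
    correction-factor error.  By the delta method the standard error of
    the corrected mean  t̄_c = 100 · t̄ / c̄  is

        SE² = SE(t̄_c|c̄)² + ( t̄_c · SE(c̄) / 100 )²

    where SE(c̄) is the control mean's standard error on the corrected
    scale (controls' corrected mean is 100 by construction).
    """
    t = np.asarray(treated_corrected, dtype=float)
    c = np.asarray(controls_corrected, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValidationError("corrected_group_mean needs n >= 2 in both groups")
    mean = float(t.mean())
    se_t = t.std(ddof=1) / math.sqrt(t.size)
    se_c = c.std(ddof=1) / math.sqrt(c.size)
    sem = float(math.hypot(se_t, mean * se_c / 100.0))
    return {"mean": mean, "sem": sem, "n": int(t.size), "n_controls": int(c.size)}


def relative_fluorescence(
    ts_values: Sequence[float],
    nontransgenic_values: Sequence[float],
) -> dict:
    """Absolute-mode comparison against non-transgenic controls.

    No baseline normalization: reports group means +/- sem and the
    transgenic / non-transgenic ratio of means.  sem is undefined (None)
    for singleton groups.
    """
    a = np.asarray(ts_values, dtype=float)
    b = np.asarray(nontransgenic_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")

    def _sem(x: np.ndarray) -> float | None:
        return None if x.size < 2 else float(x.std(ddof=1) / math.sqrt(x.size))

    return {
        "transgenic_mean": float(a.mean()),
        "transgenic_sem": _sem(a),
        "nontransgenic_mean": float(b.mean()),
        "nontransgenic_sem": _sem(b),
        "ratio": float(a.mean() / b.mean()) if b.mean() != 0 else math.inf,
    }
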