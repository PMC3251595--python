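"""End-to-end processing: scan sessions -> tidy subject time courses.

Order of operations (each step delegated to its module):

1. pool negative-control grids per channel across sessions and estimate
   the background threshold;
2. per scan, compute Total Signal; average replicate scans;
3. normalize each transgenic subject to its own baseline session;
4. apply the untreated-control correction factor per timepoint;
5. assemble a quality report (S:B, classical Z', per-individual Z',
   state-transition Z per condition and timepoint).

Non-fluorescent negative controls are carried through with raw Total
Signal only — percentages of a detection-limit baseline would be
meaningless, so they are excluded from normalization and group statistics.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from . import assay_quality, signal_core
from .assay_quality import PerIndividualZPrime, QualityReport
from .normalization import (
    SubjectTimeCourse,
    TimeCoursePoint,
    baseline_normalize,
    control_correct_timecourses,
)
from .plate_io import PlateLayout, ScanSession, ValidationError, WellAssignment
from .signal_core import BackgroundModel, MAX_REGION, estimate_background

__all__ = ["merge_layouts", "estimate_backgrounds", "process_sessions", "quality_report"]


def merge_layouts(layouts: Sequence[PlateLayout]) -> dict[str, WellAssignment]:
    """Subject -> assignment across plates (subjects unique per dataset)."""
    merged: dict[str, WellAssignment] = {}
    for layout in layouts:
        for a in layout.assignments.values():
            if a.subject_id in merged:
                raise ValidationError(
                    f"subject {a.subject_id} appears on more than one plate"
                )
            merged[a.subject_id] = a
    return merged


def estimate_backgrounds(
    sessions: Sequence[ScanSession],
    assignments: Mapping[str, WellAssignment],
) -> dict[str, BackgroundModel]:
    """Per-channel detection thresholds from pooled negative-control grids."""
    by_channel: dict[str, list] = {}
    for s in sessions:
        for g in s.grids:
            a = assignments.get(g.subject_id)
            if a is not None and a.group == "NEGATIVE_CONTROL":
                by_channel.setdefault(g.channel.name, []).append(g)
    if not by_channel:
        raise ValidationError(
            "no negative controls: cannot estimate background "
            "(layout defines no NEGATIVE_CONTROL wells with scans)"
        )
    return {ch: estimate_background(grids) for ch, grids in by_channel.items()}


def process_sessions(
    sessions: Sequence[ScanSession],
    layouts: Sequence[PlateLayout] | PlateLayout,
    fallback: str = MAX_REGION,
    baseline_session: str | None = None,
) -> list[SubjectTimeCourse]:
    """Run the full processing chain and return tidy subject time courses."""
    if isinstance(layouts, PlateLayout):
        layouts = [layouts]
    assignments = merge_layouts(layouts)
    backgrounds = estimate_backgrounds(sessions, assignments)

    courses: dict[tuple[str, str], SubjectTimeCourse] = {}
    for session in sorted(sessions, key=lambda s: s.timepoint_hpf):
        per_subject: dict[tuple[str, str], list] = {}
        for g in session.grids:
            per_subject.setdefault((g.subject_id, g.channel.name), []).append(g)
        for (subject_id, channel), grids in per_subject.items():
            a = assignments.get(subject_id)
            if a is None:
                raise ValidationError(f"subject {subject_id} not in any layout")
            bg = backgrounds[channel]
            replicates = [
                signal_core.total_signal(
                    g, bg, session_id=session.session_id, fallback=fallback
                )
                for g in grids
            ]
            result = signal_core.average_replicates(replicates)
            tc = courses.setdefault(
                (subject_id, channel),
                SubjectTimeCourse(
                    subject_id=subject_id,
                    group=a.group,
                    channel=channel,
                    condition=a.condition,
                ),
            )
            tc.points.append(
                TimeCoursePoint(
                    session_id=session.session_id,
                    timepoint_hpf=session.timepoint_hpf,
                    total_signal=result.total_signal,
                    n_signal_regions=result.n_signal_regions,
                    method=result.method,
                )
            )

    out = []
    for tc in courses.values():
        if tc.group == "NEGATIVE_CONTROL":
            tc.points.sort(key=lambda p: p.timepoint_hpf)
        else:
            baseline_normalize(tc, baseline_session=baseline_session)
        out.append(tc)
    control_correct_timecourses(out)
    out.sort(key=lambda tc: (tc.subject_id, tc.channel))
    return out


def quality_report(
    sessions: Sequence[ScanSession],
    layouts: Sequence[PlateLayout] | PlateLayout,
    timecourses: Sequence[SubjectTimeCourse] | None = None,
    baseline_timepoint: float | None = None,
) -> dict[str, QualityReport]:
    """Assemble per-channel quality reports.

    S:B ratios come from per-scan Total Signal of transgenic subjects at
    the earliest session; per-individual Z' uses each subject's replicate
    scans there against the pooled negative maxima; the classical Z'
    compares transgenic vs negative-control Total Signal across the
    population; state-transition Z is computed per (condition, timepoint)
    from corrected percentages when time courses are supplied.
    """
    if isinstance(layouts, PlateLayout):
        layouts = [layouts]
    assignments = merge_layouts(layouts)
    backgrounds = estimate_backgrounds(sessions, assignments)
    first = min(sessions, key=lambda s: s.timepoint_hpf)

    reports: dict[str, QualityReport] = {}
    for channel, bg in backgrounds.items():
        sb_values = []
        subject_scans: dict[str, list[float]] = {}
        pos_population: list[float] = []
        neg_population: list[float] = []
        for g in first.grids:
            if g.channel.name != channel:
                continue
            a = assignments[g.subject_id]
            ts = signal_core.total_signal(
                g, bg, session_id=first.session_id
            ).total_signal
            if a.group == "NEGATIVE_CONTROL":
                neg_population.append(g.max_value)
            else:
                subject_scans.setdefault(g.subject_id, []).append(ts)
                pos_population.append(ts)
                sb_values.append(signal_core.sb_ratio(ts, bg))

        report = QualityReport(channel=channel)
        if sb_values:
            arr = np.asarray(sb_values)
            report.sb_stats = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "q25": float(np.percentile(arr, 25)),
                "q50": float(np.percentile(arr, 50)),
                "q75": float(np.percentile(arr, 75)),
                "n": int(arr.size),
            }
        if len(pos_population) >= 2 and len(neg_population) >= 2:
            report.zprime_classical = assay_quality.zprime_classical(
                pos_population, neg_population
            ).value
        if subject_scans:
            report.zprime_per_individual = assay_quality.zprime_per_individual(
                subject_scans, bg.mu_neg, bg.sd_neg
            )
        if timecourses:
            by_cond: dict[tuple[str, float], list[float]] = {}
            for tc in timecourses:
                if tc.channel != channel or tc.group != "TREATED" or tc.excluded:
                    continue
                for p in tc.points:
                    if p.corrected_pct is None:
                        continue
                    if baseline_timepoint is not None and math.isclose(
                        p.timepoint_hpf, baseline_timepoint
                    ):
                        continue
                    by_cond.setdefault(
                        (tc.condition or "", p.timepoint_hpf), []
                    ).append(p.corrected_pct)
            for (condition, t), pcts in sorted(by_cond.items()):
                if len(pcts) < 2 or t == min(tp.timepoint_hpf for tc in timecourses for tp in tc.points):
                    continue
                z = assay_quality.zfactor_state_transition(pcts, 100.0)
                report.zfactor_by_condition_timepoint.append(
                    {
                        "condition": condition,
                        "timepoint_hpf": float(t),
                        "Z": z.value,
                        "n": len(pcts),
                    }
                )
        reports[channel] = report
    return reports
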