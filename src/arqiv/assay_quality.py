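"""Assay-quality statistics: S:B summaries, Z'-factor and its two
whole-organism modifications.

The classical screening-window coefficient of Zhang, Chung & Oldenburg,

    Z' = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|,

compares positive- and negative-control populations and lies in
(-inf, 1]: > 0.5 excellent, 0–0.5 acceptable, exactly 0 binary-only,
< 0 needs improvement.

Because reporter expression varies ~10x across individual fish, a
population Z' under-states what the instrument can actually resolve in a
single animal.  Two modifications address this:

* **per-individual Z'** — sigma comes from each subject's successive
  replicate scans rather than across the population, and the per-subject
  Z' values are averaged;
* **state-transition Z** — the "reference control" is each subject's own
  *prior state* and the "treated sample" its *post state* on the
  internally normalized percentage scale; when the prior state is the
  normalization anchor its percentages are all exactly 100 and its sd is
  0 by construction.

Degenerate windows (equal means) yield a -inf sentinel that is reported,
flagged, and excluded from averages — never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .plate_io import ValidationError

__all__ = [
    "ZResult",
    "PerIndividualZPrime",
    "QualityReport",
    "zprime_classical",
    "zprime_from_stats",
    "zprime_per_individual",
    "zfactor_state_transition",
    "summarize_sem",
    "paired_change_test",
    "interpret_zfactor",
    "EXCELLENT",
    "ACCEPTABLE",
    "BINARY_ONLY",
    "IMPROVE",
    "DEGENERATE",
]

EXCELLENT = "EXCELLENT"
ACCEPTABLE = "ACCEPTABLE"
BINARY_ONLY = "BINARY_ONLY"
IMPROVE = "IMPROVE"
DEGENERATE = "DEGENERATE"


def interpret_zfactor(z: float) -> str:
    """Map a Z/Z' value onto the standard quality bands."""
    if z > 1.0:
        raise ValidationError(f"Z-factor cannot exceed 1, got {z}")
    if z > 0.5:
        return EXCELLENT
    if z > 0.0:
        return ACCEPTABLE
    if z == 0.0:
        return BINARY_ONLY
    return IMPROVE


@dataclass(frozen=True)
class ZResult:
    value: float
    flags: tuple[str, ...] = ()

    @property
    def interpretation(self) -> str:
        if math.isinf(self.value):
            return IMPROVE
        return interpret_zfactor(self.value)


def zprime_from_stats(
    mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float
) -> ZResult:
    """Z' from summary statistics; equal means give the -inf sentinel."""
    if sd_pos < 0 or sd_neg < 0:
        raise ValidationError("standard deviations must be >= 0")
    window = abs(mu_pos - mu_neg)
    if window == 0:
        return ZResult(value=-math.inf, flags=(DEGENERATE,))
    return ZResult(value=1.0 - 3.0 * (sd_pos + sd_neg) / window)


def zprime_classical(
    pos: Sequence[float] | np.ndarray, neg: Sequence[float] | np.ndarray
) -> ZResult:
    """Classical Z' from raw positive- and negative-control samples.

    Sample (n-1) standard deviations; both samples need n >= 2 (use
    :func:`zprime_from_stats` when only summary statistics exist).
    """
    p = np.asarray(pos, dtype=float)
    n = np.asarray(neg, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValidationError("both control samples need n >= 2")
    return zprime_from_stats(
        p.mean(), p.std(ddof=1), n.mean(), n.std(ddof=1)
    )


@dataclass(frozen=True)
class PerIndividualZPrime:
    per_subject: Mapping[str, float]
    mean: float | None
    sem: float | None
    excluded: tuple[str, ...] = ()  # single-scan or degenerate subjects

    @property
    def n_used(self) -> int:
        return sum(1 for v in self.per_subject.values() if math.isfinite(v))


def zprime_per_individual(
    subject_scans: Mapping[str, Sequence[float]],
    neg_mu: float,
    neg_sd: float,
) -> PerIndividualZPrime:
    """Per-individual Z': each subject's sigma from its successive scans.

    ``Z'_i = 1 - 3 (sigma_i + sigma_neg) / |mu_i - mu_neg|`` with mu_i,
    sigma_i over subject i's replicate scans.  Subjects with a single scan
    are excluded with a warning entry; degenerate subjects (mean exactly
    on the negative mean) contribute a -inf sentinel that is reported but
    excluded from the mean.  The negative sample is the pooled per-scan
    maxima of negative-control wells from the same sessions, passed here
    as its mean and sd.
    """
    if neg_sd < 0:
        raise ValidationError("neg_sd must be >= 0")
    per_subject: dict[str, float] = {}
    excluded: list[str] = []
    for subject, scans in subject_scans.items():
        arr = np.asarray(list(scans), dtype=float)
        if arr.size < 2:
            excluded.append(subject)
            continue
        z = zprime_from_stats(arr.mean(), arr.std(ddof=1), neg_mu, neg_sd)
        per_subject[subject] = z.value
        if math.isinf(z.value):
            excluded.append(subject)
    finite = [v for v in per_subject.values() if math.isfinite(v)]
    mean = float(np.mean(finite)) if finite else None
    sem = summarize_sem(finite)["sem"] if finite else None
    return PerIndividualZPrime(
        per_subject=per_subject, mean=mean, sem=sem, excluded=tuple(excluded)
    )


def zfactor_state_transition(
    post_pcts: Sequence[float] | np.ndarray,
    prior_pcts: Sequence[float] | np.ndarray | float = 100.0,
) -> ZResult:
    """State-transition Z on the normalized percentage scale.

    ``post_pcts`` are the post-state percentages across fish of one
    treatment condition at one timepoint.  ``prior_pcts`` is either the
    prior state's percentages across the same fish, or a scalar anchor
    (default 100) for the case where the prior state is the baseline each
    subject is normalized to — there every prior percentage is exactly 100
    and sigma_prior = 0 by construction.  For a non-anchor reference (e.g.
    the post-ablation trough when scoring regeneration) pass that state's
    percentages and its across-fish sd is used.
    """
    post = np.asarray(post_pcts, dtype=float)
    if post.size < 2:
        raise ValidationError("state-transition Z needs n >= 2 fish")
    if np.isscalar(prior_pcts) or np.ndim(prior_pcts) == 0:
        mu_prior, sd_prior = float(prior_pcts), 0.0
    else:
        prior = np.asarray(prior_pcts, dtype=float)
        if prior.size != post.size:
            raise ValidationError(
                "prior and post states must cover the same fish "
                f"(got n={prior.size} vs n={post.size})"
            )
        mu_prior, sd_prior = float(prior.mean()), float(prior.std(ddof=1))
    return zprime_from_stats(float(post.mean()), float(post.std(ddof=1)), mu_prior, sd_prior)


def summarize_sem(values: Sequence[float] | np.ndarray) -> dict:
    """Mean and standard error (sample sd / sqrt n); sem is None at n=1."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.size < 1:
        raise ValidationError("summarize_sem needs n >= 1")
    sem = None if arr.size < 2 else float(arr.std(ddof=1) / math.sqrt(arr.size))
    return {"mean": float(arr.mean()), "sem": sem, "n": int(arr.size)}


def paired_change_test(
    pre: Sequence[float] | np.ndarray, post: Sequence[float] | np.ndarray
) -> dict:
    """Two-sided paired t-test on matched pre/post values.

    Zero difference variance leaves the p-value undefined (None) with a
    DEGENERATE flag rather than raising.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.size != b.size:
        raise ValidationError("paired test needs matched samples")
    if a.size < 2:
        raise ValidationError("paired test needs n >= 2")
    diff = b - a
    if np.allclose(diff.std(ddof=1), 0.0):
        return {"p_value": None, "t": None, "flags": (DEGENERATE,)}
    t, p = stats.ttest_rel(b, a)
    return {"p_value": float(p), "t": float(t), "flags": ()}


@dataclass
class QualityReport:
    """Serializable assay-quality summary for one channel."""

    channel: str
    sb_stats: dict = field(default_factory=dict)
    zprime_classical: float | None = None
    zprime_per_individual: PerIndividualZPrime | None = None
    zfactor_by_condition_timepoint: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _z(v):
            return "-inf" if v is not None and math.isinf(v) else v

        d: dict = {"channel": self.channel, "sb_stats": self.sb_stats}
        if self.zprime_classical is not None:
            d["zprime_classical"] = {
                "value": _z(self.zprime_classical),
                "interpretation": IMPROVE
                if math.isinf(self.zprime_classical)
                else interpret_zfactor(self.zprime_classical),
            }
        if self.zprime_per_individual is not None:
            zi = self.zprime_per_individual
            d["zprime_per_individual"] = {
                "per_subject": {k: _z(v) for k, v in sorted(zi.per_subject.items())},
                "mean": zi.mean,
                "sem": zi.sem,
                "excluded": list(zi.excluded),
                "interpretation": None
                if zi.mean is None
                else interpret_zfactor(zi.mean),
            }
        d["zfactor_by_condition_timepoint"] = [
            {**row, "Z": _z(row["Z"])} for row in self.zfactor_by_condition_timepoint
        ]
        return d

    def to_text(self) -> str:
        lines = [f"Assay quality report — channel {self.channel}"]
        if self.sb_stats:
            s = self.sb_stats
            lines.append(
                f"  S:B ratio: mean {s['mean']:.2f} ± sd {s['sd']:.2f}  "
                f"(quartiles {s['q25']:.2f} / {s['q50']:.2f} / {s['q75']:.2f}, n={s['n']})"
            )
        if self.zprime_classical is not None:
            z = self.zprime_classical
            label = IMPROVE if math.isinf(z) else interpret_zfactor(z)
            lines.append(f"  classical Z': {z:.3f}  [{label}]")
        if self.zprime_per_individual is not None and self.zprime_per_individual.mean is not None:
            zi = self.zprime_per_individual
            sem = f" ± {zi.sem:.3f} sem" if zi.sem is not None else ""
            lines.append(
                f"  per-individual Z': mean {zi.mean:.3f}{sem} over {zi.n_used} fish  "
                f"[{interpret_zfactor(zi.mean)}]"
            )
        for row in self.zfactor_by_condition_timepoint:
            z = row["Z"]
            ztxt = "-inf" if math.isinf(z) else f"{z:.3f}"
            lines.append(
                f"  state-transition Z [{row['condition']} @ {row['timepoint_hpf']:g} hpf]: {ztxt}"
            )
        return "\n".join(lines)
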