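"""Background estimation, region classification and Total Signal.

The detection limit of the instrument is estimated operationally from
non-fluorescent sibling controls: for each negative-control well the
*maximal* regional value is taken, and the background threshold is

    B = mean(maxima) + 3 * sd(maxima)        (sample sd, n - 1)

A region is "signal" when its reading strictly exceeds B.  A subject's
Total Signal (TS) for one scan is the sum of all signal regions; replicate
scans are averaged *after* per-scan TS computation.  When every region of
the experimental channel falls below B (e.g. after cell ablation), one of
two fallbacks localizes the tissue: a spatially congruent reference
channel identifies which regions to sum, or — absent a reference — the
single maximal regional value is used.  Both fallbacks mark the result
below-detection.

The signal-to-background ratio reported throughout is TS / B; B is the
stated detection limit, so S:B is "how many detection limits of signal".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .plate_io import ScanGrid, ValidationError

__all__ = [
    "BackgroundModel",
    "TotalSignalResult",
    "estimate_background",
    "background_from_maxima",
    "total_signal",
    "average_replicates",
    "sb_ratio",
    "DIRECT",
    "REFERENCE_CHANNEL",
    "MAX_REGION",
]

DIRECT = "DIRECT"
REFERENCE_CHANNEL = "REFERENCE_CHANNEL"
MAX_REGION = "MAX_REGION"


@dataclass(frozen=True)
class BackgroundModel:
    """Per-channel detection threshold derived from negative controls."""

    channel: str
    n_controls: int
    mu_neg: float
    sd_neg: float

    @property
    def threshold_B(self) -> float:
        return self.mu_neg + 3.0 * self.sd_neg

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValidationError("background model needs at least one control")
        if self.sd_neg < 0:
            raise ValidationError("sd_neg must be >= 0")

    @property
    def single_control(self) -> bool:
        """True when sd was undefined (one control) and taken as 0."""
        return self.n_controls == 1


@dataclass(frozen=True)
class TotalSignalResult:
    subject_id: str
    session_id: str
    channel: str
    total_signal: float
    n_signal_regions: int
    method: str = DIRECT
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.total_signal < 0:
            raise ValidationError("total_signal must be >= 0")
        if self.method == DIRECT and self.n_signal_regions < 1 and not self.below_detection:
            raise ValidationError(
                "DIRECT result with no signal regions must be below_detection"
            )


def background_from_maxima(
    maxima: Sequence[float] | np.ndarray, channel: str
) -> BackgroundModel:
    """Build a :class:`BackgroundModel` from per-well maximal regional values."""
    arr = np.asarray(maxima, dtype=float)
    if arr.size == 0:
        raise ValidationError("no negative controls: cannot estimate background")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValidationError("negative-control maxima must be finite and >= 0")
    mu = float(arr.mean())
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    return BackgroundModel(channel=channel, n_controls=int(arr.size), mu_neg=mu, sd_neg=sd)


def estimate_background(neg_grids: Iterable[ScanGrid]) -> BackgroundModel:
    """Estimate the detection threshold from negative-control scan grids.

    Takes the maximal regional value of each grid first, then
    mean + 3 * sample sd over those per-well maxima.  All grids must share
    a channel.  A single control is accepted (sd taken as 0) but flagged
    via :attr:`BackgroundModel.single_control`.
    """
    grids = list(neg_grids)
    if not grids:
        raise ValidationError("no negative controls: cannot estimate background")
    channels = {g.channel.name for g in grids}
    if len(channels) > 1:
        raise ValidationError(
            f"negative controls span multiple channels: {sorted(channels)}"
        )
    maxima = [g.max_value for g in grids]
    return background_from_maxima(maxima, channel=channels.pop())


def total_signal(
    grid: ScanGrid,
    bg: BackgroundModel,
    *,
    session_id: str = "",
    fallback: str = MAX_REGION,
    reference_grid: ScanGrid | None = None,
    reference_bg: BackgroundModel | None = None,
) -> TotalSignalResult:
    """Compute a subject's Total Signal for one scan.

    DIRECT mode sums every region strictly above ``bg.threshold_B``.  If no
    region qualifies the requested fallback applies: ``REFERENCE_CHANNEL``
    sums the experimental channel over the regions where a spatially
    congruent reference channel exceeds *its own* threshold; ``MAX_REGION``
    returns the single maximal regional value.  Fallback results are marked
    ``below_detection``.  Ties at exactly B count as background.
    """
    if grid.channel.name != bg.channel:
        raise ValidationError(
            f"grid channel {grid.channel.name!r} != background channel {bg.channel!r}"
        )
    B = bg.threshold_B
    values = np.asarray(grid.values)
    signal = values > B
    if signal.any():
        return TotalSignalResult(
            subject_id=grid.subject_id,
            session_id=session_id,
            channel=grid.channel.name,
            total_signal=float(values[signal].sum()),
            n_signal_regions=int(signal.sum()),
            method=DIRECT,
        )

    if fallback == REFERENCE_CHANNEL:
        if reference_grid is None or reference_bg is None:
            raise ValidationError(
                "REFERENCE_CHANNEL fallback requires reference_grid and reference_bg"
            )
        if reference_grid.pattern_n != grid.pattern_n:
            raise ValidationError(
                f"pattern_n mismatch: experimental {grid.pattern_n} vs "
                f"reference {reference_grid.pattern_n}"
            )
        ref_signal = np.asarray(reference_grid.values) > reference_bg.threshold_B
        ts = float(values[ref_signal].sum()) if ref_signal.any() else 0.0
        return TotalSignalResult(
            subject_id=grid.subject_id,
            session_id=session_id,
            channel=grid.channel.name,
            total_signal=ts,
            n_signal_regions=int(ref_signal.sum()),
            method=REFERENCE_CHANNEL,
            below_detection=True,
        )
    if fallback == MAX_REGION:
        return TotalSignalResult(
            subject_id=grid.subject_id,
            session_id=session_id,
            channel=grid.channel.name,
            total_signal=float(values.max()),
            n_signal_regions=0,
            method=MAX_REGION,
            below_detection=True,
        )
    raise ValidationError(f"unknown fallback policy {fallback!r}")


def average_replicates(results: Sequence[TotalSignalResult]) -> TotalSignalResult:
    """Average replicate scans of one subject/session/channel.

    Total Signal is the arithmetic mean across replicates.  The result is
    below-detection only if every replicate was; the reported method is the
    majority method across replicates, with ties resolved in favour of
    DIRECT, then REFERENCE_CHANNEL.
    """
    if not results:
        raise ValidationError("no replicates to average")
    keys = {(r.subject_id, r.session_id, r.channel) for r in results}
    if len(keys) > 1:
        raise ValidationError(f"replicates mix subjects/sessions/channels: {sorted(keys)}")
    subject_id, session_id, channel = keys.pop()
    ts = float(np.mean([r.total_signal for r in results]))
    precedence = {DIRECT: 0, REFERENCE_CHANNEL: 1, MAX_REGION: 2}
    counts: dict[str, int] = {}
    for r in results:
        counts[r.method] = counts.get(r.method, 0) + 1
    method = min(counts, key=lambda m: (-counts[m], precedence[m]))
    below = all(r.below_detection for r in results)
    n_regions = int(round(np.mean([r.n_signal_regions for r in results])))
    return TotalSignalResult(
        subject_id=subject_id,
        session_id=session_id,
        channel=channel,
        total_signal=ts,
        n_signal_regions=n_regions,
        method=method,
        below_detection=below,
    )


def sb_ratio(ts: TotalSignalResult | float, bg: BackgroundModel) -> float:
    """Signal-to-background ratio: Total Signal over the detection threshold."""
    B = bg.threshold_B
    if B <= 0:
        raise ValidationError("background threshold is zero")
    value = ts.total_signal if isinstance(ts, TotalSignalResult) else float(ts)
    return value / B
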