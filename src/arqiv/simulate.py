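"""Synthetic plate-data generator with ground truth.

Emulates the statistical structure of whole-organism plate-reader data so
the processing pipeline, quality statistics and hit-calling rules can be
exercised against known truth:

* **inter-individual expression** — each subject's true baseline signal is
  lognormal (strictly positive, right-skewed); the default ``sigma_log``
  of 0.6 puts the central 95 % of hemizygous siblings across a >= 10-fold
  range, the order-of-magnitude spread seen between clutchmates;
* **spatial profile** — a GLOBAL reporter spreads signal over every region
  the fish covers, a REGIONAL(k) reporter concentrates it in ``k``
  regions at a random in-well position (re-drawn each session: fish are
  re-arrayed between sessions, but anesthetized fish hold position across
  replicate scans within a session);
* **noise** — additive per-region autofluorescence (Gaussian, truncated
  at 0), multiplicative within-session replicate noise (``replicate_cv``),
  a per-subject per-session lognormal factor (``session_sd_log``,
  re-array/orientation/anesthesia variation between sessions), and a
  plate-wide lognormal drift shared by all fish in a session
  (``shared_drift_sd_log``), which is exactly what the untreated-control
  correction factor exists to remove;
* **time-course models** — prodrug ablation with saturating regeneration,
  Hill-type dose response, delayed exponential induction, and
  multiplicative oxidative-stress effects, each returning the true
  fraction-of-baseline trajectory recorded per subject as ground truth.

All randomness flows from a single seeded generator; identical seeds give
byte-identical emitted datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_io import (
    Channel,
    PlateLayout,
    ScanGrid,
    ScanSession,
    ValidationError,
    WellAssignment,
    write_layout,
    write_regional_export,
)

__all__ = [
    "SimulationConfig",
    "AblationRegen",
    "DoseResponse",
    "Induction",
    "Ros",
    "SimSubject",
    "SimulatedDataset",
    "make_population",
    "simulate_timecourse",
    "render_scan",
    "render_session",
    "emit_dataset",
    "ablation_scenario",
    "dose_response_scenario",
    "induction_screen",
    "sb_regime_config",
]

GLOBAL = "GLOBAL"
REGIONAL = "REGIONAL"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated assay.

    Defaults model a strong regional reporter (e.g. YFP in rod
    photoreceptors) read with a 2x2 pattern in black U-bottom plates:
    median expression 5000 RFU against a detection threshold around
    45 RFU, i.e. a signal-to-background regime of roughly 100:1.
    """

    seed: int
    n_per_group: int = 24
    n_negative: int = 8
    pattern_n: int = 2
    spatial_profile: str = REGIONAL
    n_signal_regions: int = 1
    expression_median_rfu: float = 5000.0
    sigma_log: float = 0.6
    replicate_cv: float = 0.05
    session_sd_log: float = 0.10
    shared_drift_sd_log: float = 0.05
    autofluor_mean_rfu: float = 20.0
    autofluor_sd_rfu: float = 8.0
    n_replicates: int = 3
    channel: str = "YFP"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory (no silent nondeterminism)")
        if not 1 <= self.pattern_n <= 7:
            raise ValidationError("pattern_n must be in 1..7")
        if self.spatial_profile not in (GLOBAL, REGIONAL):
            raise ValidationError("spatial_profile must be GLOBAL or REGIONAL")
        if self.n_signal_regions > self.pattern_n**2:
            raise ValidationError(
                f"REGIONAL({self.n_signal_regions}) exceeds "
                f"{self.pattern_n}x{self.pattern_n} regions"
            )
        for name in ("sigma_log", "replicate_cv", "session_sd_log",
                     "shared_drift_sd_log", "autofluor_sd_rfu"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.expression_median_rfu <= 0 or self.autofluor_mean_rfu < 0:
            raise ValidationError("expression/autofluorescence levels must be valid")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sb_regime_config(seed: int, sb_ratio: float, **overrides) -> SimulationConfig:
    """Config whose median expression targets a given S:B regime.

    The detection threshold implied by the autofluorescence parameters is
    approximated from the max-statistics of the per-region noise; the
    median expression is set to ``sb_ratio`` times that threshold.
    """
    base = SimulationConfig(seed=seed, **overrides)
    n_regions = base.pattern_n**2
    # expected max of n iid truncated normals, rough normal approximation
    a, s = base.autofluor_mean_rfu, base.autofluor_sd_rfu
    e_max = a + s * float(np.sqrt(2 * np.log(max(n_regions, 2))))
    sd_max = 0.7 * s
    threshold = e_max + 3 * sd_max
    return replace(base, expression_median_rfu=sb_ratio * threshold)


# ---------------------------------------------------------------------------
# time-course models (deterministic; fraction of baseline)


@dataclass(frozen=True)
class AblationRegen:
    """Prodrug ablation followed by saturating regeneration.

    During the treatment window the true signal declines exponentially
    from 1 toward ``floor_fraction`` (rate ``decline_rate_per_h``); after
    washout it recovers toward 1 as ``1 - (1 - f_end) * exp(-r * dt)``.
    """

    treat_start_hpf: float
    treat_window_h: float = 24.0
    floor_fraction: float = 0.1
    decline_rate_per_h: float = 0.4
    recovery_rate_per_h: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.floor_fraction <= 1:
            raise ValidationError("floor_fraction must be in [0, 1]")
        if self.decline_rate_per_h < 0 or self.recovery_rate_per_h < 0:
            raise ValidationError("rates must be >= 0")

    def fraction(self, t: float) -> float:
        t0, t1 = self.treat_start_hpf, self.treat_start_hpf + self.treat_window_h
        if t <= t0:
            return 1.0
        f, d = self.floor_fraction, self.decline_rate_per_h
        if t <= t1:
            return f + (1.0 - f) * math.exp(-d * (t - t0))
        f_end = f + (1.0 - f) * math.exp(-d * self.treat_window_h)
        return 1.0 - (1.0 - f_end) * math.exp(-self.recovery_rate_per_h * (t - t1))


@dataclass(frozen=True)
class DoseResponse:
    """Hill-type inhibition settling to a dose-dependent plateau.

    Plateau = 1 / (1 + (dose / ic50)^hill); the trajectory relaxes from 1
    toward the plateau at ``transition_rate_per_h`` after treatment onset.
    """

    dose: float
    ic50: float
    hill: float = 1.0
    onset_hpf: float = 0.0
    transition_rate_per_h: float = 0.1

    def __post_init__(self) -> None:
        if self.dose < 0 or self.ic50 <= 0 or self.hill <= 0:
            raise ValidationError("dose >= 0, ic50 > 0, hill > 0 required")
        if self.transition_rate_per_h < 0:
            raise ValidationError("rates must be >= 0")

    @property
    def plateau(self) -> float:
        if self.dose == 0:
            return 1.0
        return 1.0 / (1.0 + (self.dose / self.ic50) ** self.hill)

    def fraction(self, t: float) -> float:
        if t <= self.onset_hpf or self.dose == 0:
            return 1.0
        p = self.plateau
        return p + (1.0 - p) * math.exp(-self.transition_rate_per_h * (t - self.onset_hpf))


@dataclass(frozen=True)
class Induction:
    """Baseline until onset, then exponential rise to ``amplitude`` x."""

    onset_h: float
    amplitude: float
    rise_rate_per_h: float = 0.1

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.rise_rate_per_h < 0:
            raise ValidationError("amplitude and rise rate must be >= 0")

    def fraction(self, t: float) -> float:
        if t <= self.onset_h:
            return 1.0
        return 1.0 + (self.amplitude - 1.0) * (
            1.0 - math.exp(-self.rise_rate_per_h * (t - self.onset_h))
        )


@dataclass(frozen=True)
class Ros:
    """Multiplicative oxidative-stress model for dye-based readouts.

    The readout is baseline x the product of applicable stressor effects,
    x ``scavenger_multiplier`` when co-treated with a scavenger.
    """

    stressor_effects: tuple[float, ...] = ()
    scavenger_multiplier: float = 1.0
    scavenger_cotreated: bool = False
    exposure_hpf: float = 0.0

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.stressor_effects) or self.scavenger_multiplier < 0:
            raise ValidationError("effects must be >= 0")

    def fraction(self, t: float) -> float:
        if t < self.exposure_hpf:
            return 1.0
        f = 1.0
        for e in self.stressor_effects:
            f *= e
        if self.scavenger_cotreated:
            f *= self.scavenger_multiplier
        return f


FLAT = None  # untreated: trajectory identically 1


def simulate_timecourse(model, times: Sequence[float], rng=None) -> np.ndarray:
    """Evaluate a time-course model at increasing times (fraction of
    baseline).  Models are deterministic; ``rng`` is accepted for API
    symmetry and unused."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if model is FLAT:
        return np.ones_like(t)
    return np.array([model.fraction(x) for x in t])


# ---------------------------------------------------------------------------
# population and rendering


@dataclass
class SimSubject:
    subject_id: str
    group: str
    condition: str | None
    expression_rfu: float  # true baseline Total Signal (0 for negatives)
    model: object = FLAT
    dose: float | None = None


def make_population(config: SimulationConfig, rng: np.random.Generator,
                    groups: Sequence[tuple[str, str | None, int, object]] | None = None
                    ) -> list[SimSubject]:
    """Draw a population with lognormal inter-individual expression.

    ``groups`` is a sequence of (group, condition, n, model) tuples; the
    default is n_negative NEGATIVE_CONTROL plus n_per_group untreated
    TRANSGENIC_CONTROL fish.  Deterministic under the generator state.
    """
    if groups is None:
        groups = [
            ("NEGATIVE_CONTROL", None, config.n_negative, FLAT),
            ("TRANSGENIC_CONTROL", None, config.n_per_group, FLAT),
        ]
    subjects: list[SimSubject] = []
    i = 0
    for group, condition, n, model in groups:
        for _ in range(n):
            i += 1
            if group == "NEGATIVE_CONTROL":
                expr = 0.0
            else:
                expr = float(
                    config.expression_median_rfu
                    * np.exp(rng.normal(0.0, config.sigma_log))
                )
            subjects.append(
                SimSubject(
                    subject_id=f"fish-{i:03d}",
                    group=group,
                    condition=condition,
                    expression_rfu=expr,
                    model=model,
                )
            )
    return subjects


def _signal_regions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n_regions = config.pattern_n**2
    if config.spatial_profile == GLOBAL:
        return np.arange(n_regions)
    return rng.choice(n_regions, size=config.n_signal_regions, replace=False)


def render_scan(
    subject: SimSubject,
    timepoint: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    regions: np.ndarray | None = None,
    signal_scale: float = 1.0,
    well_id: str = "A1",
    replicate_index: int = 1,
) -> ScanGrid:
    """Render one replicate scan of one subject as a :class:`ScanGrid`.

    The subject's true signal at ``timepoint`` (expression x model
    fraction x ``signal_scale``) is spread over the occupied regions;
    every region receives truncated-Gaussian autofluorescence and signal
    regions receive multiplicative replicate noise.
    """
    n_regions = config.pattern_n**2
    if regions is None:
        regions = _signal_regions(config, rng)
    if len(regions) > n_regions:
        raise ValidationError("more signal regions than grid regions")
    fraction = 1.0 if subject.model is FLAT else subject.model.fraction(timepoint)
    true_signal = subject.expression_rfu * fraction * signal_scale
    values = rng.normal(config.autofluor_mean_rfu, config.autofluor_sd_rfu, n_regions)
    np.maximum(values, 0.0, out=values)
    if true_signal > 0:
        per_region = true_signal / len(regions)
        noise = rng.normal(1.0, config.replicate_cv, len(regions))
        values[np.asarray(regions)] += per_region * np.maximum(noise, 0.0)
    return ScanGrid(
        well_id=well_id,
        subject_id=subject.subject_id,
        channel=Channel(name=config.channel),
        pattern_n=config.pattern_n,
        values=[float(v) for v in values],
        replicate_index=replicate_index,
    )


def render_session(
    subjects: Sequence[SimSubject],
    wells: Mapping[str, str],
    timepoint: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    session_id: str,
) -> ScanSession:
    """Render all replicate scans of all subjects at one timepoint.

    Per session: one shared plate-wide drift factor, and per subject one
    session factor and one in-well position (held across replicates).
    """
    drift = float(np.exp(rng.normal(0.0, config.shared_drift_sd_log)))
    grids: list[ScanGrid] = []
    for subject in subjects:
        session_factor = drift * float(np.exp(rng.normal(0.0, config.session_sd_log)))
        regions = _signal_regions(config, rng)
        for rep in range(1, config.n_replicates + 1):
            grids.append(
                render_scan(
                    subject,
                    timepoint,
                    config,
                    rng,
                    regions=regions,
                    signal_scale=session_factor,
                    well_id=wells[subject.subject_id],
                    replicate_index=rep,
                )
            )
    return ScanSession(session_id=session_id, timepoint_hpf=timepoint, grids=grids)


# ---------------------------------------------------------------------------
# datasets and scenarios


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    subjects: list[SimSubject]
    layouts: list[PlateLayout]
    sessions: list[ScanSession]
    truth: pd.DataFrame  # one row per subject x timepoint
    timepoints: tuple[float, ...]


def _layouts_for(subjects: Sequence[SimSubject], wells_per_plate: int = 96
                 ) -> tuple[list[PlateLayout], dict[str, str]]:
    rows = "ABCDEFGH"
    cols = range(1, 13)
    well_ids = [f"{r}{c}" for r in rows for c in cols][:wells_per_plate]
    layouts: list[PlateLayout] = []
    well_of: dict[str, str] = {}
    for p in range(0, len(subjects), wells_per_plate):
        chunk = subjects[p : p + wells_per_plate]
        assignments = {}
        for well, s in zip(well_ids, chunk):
            assignments[well] = WellAssignment(
                subject_id=s.subject_id,
                group=s.group,
                condition=s.condition,
            )
            well_of[s.subject_id] = well
        layouts.append(
            PlateLayout(plate_id=f"P{p // wells_per_plate + 1}", assignments=assignments)
        )
    return layouts, well_of


def _build_dataset(
    config: SimulationConfig,
    groups: Sequence[tuple[str, str | None, int, object]],
    timepoints: Sequence[float],
    doses: Mapping[str, float] | None = None,
) -> SimulatedDataset:
    rng = config.rng()
    subjects = make_population(config, rng, groups=groups)
    if doses:
        for s in subjects:
            s.dose = doses.get(s.condition or "", None)
    layouts, well_of = _layouts_for(subjects)
    sessions = [
        render_session(subjects, well_of, t, config, rng, session_id=f"S{i + 1}")
        for i, t in enumerate(timepoints)
    ]
    truth_rows = []
    for s in subjects:
        for t in timepoints:
            fraction = 1.0 if s.model is FLAT else s.model.fraction(t)
            truth_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "condition": "" if s.condition is None else s.condition,
                    "dose": "" if s.dose is None else repr(float(s.dose)),
                    "timepoint_hpf": repr(float(t)),
                    "true_expression_rfu": repr(float(s.expression_rfu)),
                    "true_fraction_of_baseline": repr(float(fraction)),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        config=config,
        subjects=subjects,
        layouts=layouts,
        sessions=sessions,
        truth=truth,
        timepoints=tuple(float(t) for t in timepoints),
    )


def ablation_scenario(
    seed: int,
    n_per_group: int = 24,
    floor_fraction: float = 0.1,
    treat_start_hpf: float = 120.0,
    treat_window_h: float = 24.0,
    recovery_rate_per_h: float = 0.01,
    timepoints: Sequence[float] = (120.0, 144.0, 192.0, 240.0, 264.0),
    **overrides,
) -> SimulatedDataset:
    """Prodrug ablation/regeneration assay.

    Baseline scan just before a 24 h prodrug window starting at 5 dpf
    (120 hpf), a post-treatment scan at washout (the trough), then
    recovery scans.  Treated fish fall to ``floor_fraction`` of baseline
    and recover slowly; untreated transgenic controls and non-fluorescent
    negatives ride along.

    The default expression median models a strong, pre-sorted reporter
    cohort (~300 detection limits at baseline) so that fish stay well
    above detection even at a deep trough — the screening practice of
    eliminating low expressers when arraying fish.  Autofluorescence
    inside the occupied region is summed into Total Signal by design (the
    method excludes background *regions*, it does not subtract background
    within signal regions), so a weak-expresser cohort would read a deep
    trough slightly high; see the methods note.
    """
    overrides.setdefault("expression_median_rfu", 15000.0)
    config = SimulationConfig(seed=seed, n_per_group=n_per_group, **overrides)
    model = AblationRegen(
        treat_start_hpf=treat_start_hpf,
        treat_window_h=treat_window_h,
        floor_fraction=floor_fraction,
        recovery_rate_per_h=recovery_rate_per_h,
    )
    groups = [
        ("NEGATIVE_CONTROL", None, config.n_negative, FLAT),
        ("TRANSGENIC_CONTROL", None, config.n_per_group, FLAT),
        ("TREATED", "MTZ", config.n_per_group, model),
    ]
    return _build_dataset(config, groups, timepoints)


def dose_response_scenario(
    seed: int,
    doses: Sequence[float] = (5.0, 10.0, 25.0, 50.0, 100.0),
    n_per_dose: int = 16,
    ic50: float = 10.0,
    hill: float = 1.0,
    onset_hpf: float = 48.0,
    timepoints: Sequence[float] = (48.0, 72.0, 96.0, 120.0),
    **overrides,
) -> SimulatedDataset:
    """Graded inhibitor series against an untreated dose-0 control group.

    Pre-treatment scan at 48 hpf, daily scans during treatment; each dose
    group settles toward its Hill plateau 1 / (1 + (dose/ic50)^hill).
    """
    config = SimulationConfig(seed=seed, n_per_group=n_per_dose, **overrides)
    groups: list[tuple] = [
        ("NEGATIVE_CONTROL", None, config.n_negative, FLAT),
        ("TRANSGENIC_CONTROL", "dose-0", n_per_dose, FLAT),
    ]
    dose_of = {"dose-0": 0.0}
    for d in doses:
        label = f"dose-{d:g}"
        dose_of[label] = float(d)
        groups.append(
            ("TREATED", label, n_per_dose,
             DoseResponse(dose=d, ic50=ic50, hill=hill, onset_hpf=onset_hpf))
        )
    return _build_dataset(config, groups, timepoints, doses=dose_of)


def induction_screen(
    seed: int,
    n_null: int = 500,
    n_pos: int = 100,
    effect_sd: float = 5.0,
    onset_hpf: float = 96.0,
    timepoints: Sequence[float] = (96.0, 102.0, 108.0, 114.0, 120.0),
    rise_rate_per_h: float = 0.05,
    **overrides,
) -> tuple[SimulatedDataset, float]:
    """Heat-shock induction screen for hit-calling operating characteristics.

    Null subjects (reporter-only, no induction) are flat; positive
    subjects carry an induced rise whose *noise-free* expression slope
    equals ``effect_sd`` times the across-fish standard deviation of the
    null slopes under the configured noise.  That null slope sd is
    obtained from a pilot simulation of the null subjects (same seed
    stream), so the effect size is stated in units of the controls' own
    variability, exactly as a k-sigma hit rule measures it.

    Returns the dataset and the calibrated true positive slope (%/h).
    """
    from .pipeline import process_sessions
    from .screen import ols_slope

    config = SimulationConfig(seed=seed, n_per_group=n_null, **overrides)
    t = np.asarray(timepoints, dtype=float)

    # pilot: null-only screen to measure the control slope sd
    pilot_groups = [
        ("NEGATIVE_CONTROL", None, config.n_negative, FLAT),
        ("TRANSGENIC_CONTROL", None, n_null, FLAT),
    ]
    pilot = _build_dataset(config, pilot_groups, timepoints)
    courses = process_sessions(pilot.sessions, pilot.layouts)
    null_slopes = [
        ols_slope(
            [p.timepoint_hpf for p in tc.points],
            [p.corrected_pct for p in tc.points],
        )
        for tc in courses
        if tc.group == "TRANSGENIC_CONTROL" and not tc.excluded
    ]
    sigma_slope = float(np.std(null_slopes, ddof=1))

    # calibrate the induction amplitude: slope of the deterministic
    # percentage trajectory 100*f(t) must equal effect_sd * sigma_slope
    probe = Induction(onset_h=onset_hpf, amplitude=2.0, rise_rate_per_h=rise_rate_per_h)
    g = 100.0 * simulate_timecourse(probe, t)
    slope_per_amp = ols_slope(t, g) / (probe.amplitude - 1.0)
    target_slope = effect_sd * sigma_slope
    amplitude = 1.0 + target_slope / slope_per_amp

    model = Induction(onset_h=onset_hpf, amplitude=amplitude, rise_rate_per_h=rise_rate_per_h)
    groups = [
        ("NEGATIVE_CONTROL", None, config.n_negative, FLAT),
        ("TRANSGENIC_CONTROL", None, n_null, FLAT),
        ("TREATED", "heat-shock", n_pos, model),
    ]
    dataset = _build_dataset(config, groups, timepoints)
    return dataset, target_slope


def emit_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset to disk: regional export (canonical
    dialect), one layout YAML per plate, and the truth table.  Output is
    byte-identical under identical seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    export = out / "regional_export.csv"
    write_regional_export(dataset.sessions, export)
    paths["export"] = export
    for layout in dataset.layouts:
        p = out / f"layout_{layout.plate_id}.yaml"
        write_layout(layout, p)
        paths[f"layout_{layout.plate_id}"] = p
    truth = out / "truth.tsv"
    dataset.truth.to_csv(truth, sep="\t", index=False, lineterminator="\n")
    paths["truth"] = truth
    return paths
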