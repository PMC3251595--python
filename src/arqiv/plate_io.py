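"""Data model and file I/O for regional plate-scan data.

A monochromator plate reader operating in regional mode reports, for every
well, an ``n x n`` grid of relative-fluorescence-unit (RFU) readings instead
of a single number.  Regional readout is what makes whole-organism assays
possible: a larva rests at a random position and orientation inside its
well, and only the sub-well regions it occupies carry reporter signal.

This module defines the atomic measurement (:class:`ScanGrid`), the plate
layout mapping wells to subjects and experimental groups
(:class:`PlateLayout`), scan sessions grouping grids taken at one timepoint
(:class:`ScanSession`), and tabular readers/writers for the canonical
regional-export format and the tidy long-format results table.

Conventions (documented, versioned as dialect ``arqiv-v1``):

* regions are indexed row-major, 0-based, ``(row, col)`` with row 0 nearest
  the plate's row label;
* well IDs are letter+number (``A1``), case-insensitive on read and
  normalized to upper case on write;
* time is stored in hours post fertilization (hpf) as float; days post
  fertilization convert at the boundary (``dpf * 24``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Channel",
    "Acquisition",
    "ScanGrid",
    "WellAssignment",
    "PlateLayout",
    "ScanSession",
    "Dialect",
    "CANONICAL_DIALECT",
    "GROUPS",
    "FormatError",
    "ValidationError",
    "read_regional_export",
    "write_regional_export",
    "read_layout",
    "write_layout",
    "write_tidy",
    "read_tidy",
    "normalize_well_id",
    "dpf_to_hpf",
]

#: Allowed experimental group labels for wells in a plate layout.
GROUPS = (
    "NEGATIVE_CONTROL",      # non-fluorescent sibling; defines the detection limit
    "TRANSGENIC_CONTROL",    # untreated transgenic; anchors the correction factor
    "TREATED",               # experimental condition (carries a condition label)
    "REFERENCE_CHANNEL_ONLY",  # ratiometric reference reporter only
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular schema."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant (e.g. negative RFU)."""


def normalize_well_id(well: str) -> str:
    """Normalize a well identifier like ``'a01'`` to ``'A1'``."""
    well = str(well).strip().upper()
    if len(well) < 2 or not well[0].isalpha() or not well[1:].isdigit():
        raise ValidationError(f"malformed well id: {well!r}")
    return f"{well[0]}{int(well[1:])}"


def dpf_to_hpf(dpf: float) -> float:
    """Convert days post fertilization to hours post fertilization."""
    return float(dpf) * 24.0


@dataclass(frozen=True)
class Channel:
    """A detection channel: fluorophore name plus monochromator settings."""

    name: str
    excitation_nm: float = float("nan")
    emission_nm: float = float("nan")
    excitation_bw_nm: float = float("nan")
    emission_bw_nm: float = float("nan")


@dataclass(frozen=True)
class Acquisition:
    """Instrument acquisition parameters shared by grids of one channel."""

    flashes: int = 5
    settle_ms: float = 40.0
    gain: float = 100.0
    z_focus_um: float = 20000.0


@dataclass
class ScanGrid:
    """One well's ``pattern_n x pattern_n`` regional RFU readings.

    ``values`` is row-major with ``pattern_n**2`` entries, all finite and
    non-negative.  ``pattern_n`` may range from 1 (single whole-well read)
    to 7, the practical range for 96-well regional scanning.
    """

    well_id: str
    subject_id: str
    channel: Channel
    pattern_n: int
    values: list[float]
    acquisition: Acquisition = field(default_factory=Acquisition)
    replicate_index: int = 1

    def __post_init__(self) -> None:
        self.well_id = normalize_well_id(self.well_id)
        if not 1 <= int(self.pattern_n) <= 7:
            raise ValidationError(
                f"pattern_n must be in 1..7, got {self.pattern_n} (well {self.well_id})"
            )
        self.pattern_n = int(self.pattern_n)
        self.values = [float(v) for v in self.values]
        if len(self.values) != self.pattern_n**2:
            raise ValidationError(
                f"well {self.well_id}: expected {self.pattern_n ** 2} regional values, "
                f"got {len(self.values)}"
            )
        for i, v in enumerate(self.values):
            if not math.isfinite(v) or v < 0:
                row, col = divmod(i, self.pattern_n)
                raise ValidationError(
                    f"well {self.well_id} region ({row},{col}): invalid RFU {v!r} "
                    "(must be finite and >= 0)"
                )

    @property
    def max_value(self) -> float:
        """Maximal regional value — the quantity background estimation uses."""
        return max(self.values)

    def value_at(self, row: int, col: int) -> float:
        return self.values[row * self.pattern_n + col]


@dataclass(frozen=True)
class WellAssignment:
    subject_id: str
    group: str
    channels: tuple[str, ...] = ()
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; allowed: {', '.join(GROUPS)}"
            )


@dataclass
class PlateLayout:
    """Well -> subject/group assignment for one plate.

    Each well is assigned at most once and each subject occupies exactly one
    well per plate.  At least one NEGATIVE_CONTROL well is expected so that a
    background (detection-limit) model can be estimated; a layout without one
    is legal but flagged, and background estimation will fail loudly later.
    """

    plate_id: str
    assignments: dict[str, WellAssignment] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        normalized: dict[str, WellAssignment] = {}
        seen_subjects: dict[str, str] = {}
        for well, a in self.assignments.items():
            w = normalize_well_id(well)
            if w in normalized:
                raise ValidationError(f"well {w} assigned more than once")
            if a.subject_id in seen_subjects:
                raise ValidationError(
                    f"subject {a.subject_id} assigned to both "
                    f"{seen_subjects[a.subject_id]} and {w}"
                )
            seen_subjects[a.subject_id] = w
            normalized[w] = a
        self.assignments = normalized
        if not self.wells_in_group("NEGATIVE_CONTROL"):
            self.warnings.append(
                "layout has no NEGATIVE_CONTROL wells; background estimation "
                "will not be possible"
            )

    def wells_in_group(self, group: str) -> list[str]:
        return [w for w, a in self.assignments.items() if a.group == group]

    def subject_for(self, well: str) -> str:
        return self.assignments[normalize_well_id(well)].subject_id

    def group_for(self, well: str) -> str:
        return self.assignments[normalize_well_id(well)].group


@dataclass
class ScanSession:
    """All grids acquired in one scanning pass at one timepoint.

    Replicate scans of the same subject/channel within a session carry
    distinct ``replicate_index`` values; all grids of one channel share
    acquisition parameters.
    """

    session_id: str
    timepoint_hpf: float
    grids: list[ScanGrid] = field(default_factory=list)
    layout_ref: str | None = None

    def __post_init__(self) -> None:
        acq_by_channel: dict[str, Acquisition] = {}
        seen: set[tuple[str, str, int]] = set()
        for g in self.grids:
            prev = acq_by_channel.setdefault(g.channel.name, g.acquisition)
            if prev != g.acquisition:
                raise ValidationError(
                    f"session {self.session_id}: grids of channel {g.channel.name} "
                    "have inconsistent acquisition parameters"
                )
            key = (g.subject_id, g.channel.name, g.replicate_index)
            if key in seen:
                raise ValidationError(
                    f"session {self.session_id}: duplicate replicate_index "
                    f"{g.replicate_index} for subject {g.subject_id} "
                    f"channel {g.channel.name}"
                )
            seen.add(key)

    def grids_for(self, subject_id: str, channel: str) -> list[ScanGrid]:
        return [
            g
            for g in self.grids
            if g.subject_id == subject_id and g.channel.name == channel
        ]


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a tabular regional export.

    The canonical dialect (``arqiv-v1``) is an artifact convention — vendor
    export schemas vary and are mapped onto these roles via a custom
    ``Dialect`` rather than auto-sniffed.
    """

    name: str = "arqiv-v1"
    sep: str = ","
    well: str = "well"
    region_row: str = "region_row"
    region_col: str = "region_col"
    value: str = "value_rfu"
    channel: str = "channel"
    session: str = "session_id"
    timepoint: str = "timepoint_hpf"
    replicate: str = "replicate"
    pattern_n: str = "pattern_n"
    subject: str = "subject_id"

    def required_columns(self) -> tuple[str, ...]:
        return (
            self.well,
            self.region_row,
            self.region_col,
            self.value,
            self.channel,
            self.session,
            self.timepoint,
            self.replicate,
            self.pattern_n,
            self.subject,
        )


CANONICAL_DIALECT = Dialect()


def read_regional_export(
    path: str | Path, dialect: Dialect = CANONICAL_DIALECT
) -> list[ScanSession]:
    """Read a tabular regional export into :class:`ScanSession` objects.

    One input row is one region of one well for one channel/replicate.
    Rows are grouped into grids by (session, well, channel, replicate);
    regions are ordered row-major regardless of row order in the file.
    Unparseable or invalid rows raise — nothing is silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep)
    missing = [c for c in dialect.required_columns() if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )

    sessions: dict[tuple[str, float], dict[tuple[str, str, int], dict]] = {}
    for idx, row in df.iterrows():
        try:
            value = float(row[dialect.value])
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path.name} row {idx}: unparseable RFU value "
                f"{row[dialect.value]!r}"
            ) from exc
        well = normalize_well_id(row[dialect.well])
        r, c = int(row[dialect.region_row]), int(row[dialect.region_col])
        if not math.isfinite(value) or value < 0:
            raise ValidationError(
                f"{path.name} row {idx}: well {well} region ({r},{c}) has "
                f"invalid RFU {value!r} (must be finite and >= 0)"
            )
        n = int(row[dialect.pattern_n])
        if not (0 <= r < n and 0 <= c < n):
            raise ValidationError(
                f"{path.name} row {idx}: region ({r},{c}) outside "
                f"{n}x{n} pattern for well {well}"
            )
        skey = (str(row[dialect.session]), float(row[dialect.timepoint]))
        gkey = (well, str(row[dialect.channel]), int(row[dialect.replicate]))
        grid = sessions.setdefault(skey, {}).setdefault(
            gkey,
            {"n": n, "subject": str(row[dialect.subject]), "values": {}},
        )
        if grid["n"] != n:
            raise ValidationError(
                f"{path.name}: inconsistent pattern_n for well {well} in "
                f"session {skey[0]}"
            )
        if (r, c) in grid["values"]:
            raise ValidationError(
                f"{path.name}: duplicate region ({r},{c}) for well {well} "
                f"session {skey[0]}"
            )
        grid["values"][(r, c)] = value

    out: list[ScanSession] = []
    for (session_id, timepoint), grids in sorted(sessions.items()):
        built: list[ScanGrid] = []
        for (well, channel, replicate), g in sorted(grids.items()):
            n = g["n"]
            expected = {(r, c) for r in range(n) for c in range(n)}
            got = set(g["values"])
            if got != expected:
                miss = sorted(expected - got)
                raise ValidationError(
                    f"session {session_id} well {well}: incomplete "
                    f"{n}x{n} grid, missing regions {miss}"
                )
            values = [g["values"][(r, c)] for r in range(n) for c in range(n)]
            built.append(
                ScanGrid(
                    well_id=well,
                    subject_id=g["subject"],
                    channel=Channel(name=channel),
                    pattern_n=n,
                    values=values,
                    replicate_index=replicate,
                )
            )
        out.append(
            ScanSession(session_id=session_id, timepoint_hpf=timepoint, grids=built)
        )
    return out


def write_regional_export(
    sessions: Iterable[ScanSession],
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
) -> None:
    """Write sessions in the canonical regional-export format (round-trips
    with :func:`read_regional_export`; deterministic row order)."""
    d = dialect
    rows = []
    for s in sorted(sessions, key=lambda s: (s.timepoint_hpf, s.session_id)):
        for g in sorted(
            s.grids, key=lambda g: (g.well_id, g.channel.name, g.replicate_index)
        ):
            n = g.pattern_n
            for i, v in enumerate(g.values):
                r, c = divmod(i, n)
                rows.append(
                    {
                        d.session: s.session_id,
                        d.timepoint: s.timepoint_hpf,
                        d.well: g.well_id,
                        d.subject: g.subject_id,
                        d.channel: g.channel.name,
                        d.replicate: g.replicate_index,
                        d.pattern_n: n,
                        d.region_row: r,
                        d.region_col: c,
                        d.value: repr(v),
                    }
                )
    df = pd.DataFrame(rows, columns=list(rows[0]) if rows else d.required_columns())
    df.to_csv(path, sep=d.sep, index=False, lineterminator="\n")


def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout from a YAML file.

    Schema::

        plate_id: P1
        wells:
          A1: {subject: fish-01, group: NEGATIVE_CONTROL, channels: [YFP]}
          A2: {subject: fish-02, group: TREATED, condition: MTZ-2.5mM,
               channels: [YFP]}
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "wells" not in doc:
        raise FormatError(f"{path.name}: layout file must map 'plate_id' and 'wells'")
    assignments = {}
    for well, spec in doc["wells"].items():
        if not isinstance(spec, dict) or "subject" not in spec or "group" not in spec:
            raise FormatError(
                f"{path.name}: well {well}: each well needs 'subject' and 'group'"
            )
        w = normalize_well_id(well)
        if w in assignments:
            raise ValidationError(f"{path.name}: well {w} assigned more than once")
        assignments[w] = WellAssignment(
            subject_id=str(spec["subject"]),
            group=str(spec["group"]),
            channels=tuple(spec.get("channels", ())),
            condition=spec.get("condition"),
        )
    return PlateLayout(plate_id=str(doc.get("plate_id", path.stem)), assignments=assignments)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    doc = {
        "plate_id": layout.plate_id,
        "wells": {
            w: {
                "subject": a.subject_id,
                "group": a.group,
                **({"condition": a.condition} if a.condition else {}),
                **({"channels": list(a.channels)} if a.channels else {}),
            }
            for w, a in sorted(layout.assignments.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# tidy long-format results table

TIDY_COLUMNS = [
    "subject_id",
    "group",
    "condition",
    "channel",
    "session_id",
    "timepoint_hpf",
    "total_signal_rfu",
    "n_signal_regions",
    "method",
    "normalized_pct",
    "corrected_pct",
    "flags",
]


def write_tidy(timecourses: Sequence, path: str | Path) -> None:
    """Write subject time courses as a tidy long-format TSV.

    One row per (subject, session, channel).  Floats are written with
    ``repr`` so the table round-trips losslessly with :func:`read_tidy`;
    flags are semicolon-joined strings, carried verbatim.
    """
    if not timecourses:
        raise ValueError("no timecourses to write")
    rows = []
    for tc in timecourses:
        for p in tc.points:
            rows.append(
                {
                    "subject_id": tc.subject_id,
                    "group": tc.group,
                    "condition": "" if tc.condition is None else tc.condition,
                    "channel": tc.channel,
                    "session_id": p.session_id,
                    "timepoint_hpf": repr(float(p.timepoint_hpf)),
                    "total_signal_rfu": repr(float(p.total_signal)),
                    "n_signal_regions": p.n_signal_regions,
                    "method": p.method,
                    "normalized_pct": "" if p.normalized_pct is None else repr(float(p.normalized_pct)),
                    "corrected_pct": "" if p.corrected_pct is None else repr(float(p.corrected_pct)),
                    "flags": ";".join(p.flags),
                }
            )
    rows.sort(key=lambda r: (r["subject_id"], float(r["timepoint_hpf"]), r["channel"]))
    df = pd.DataFrame(rows, columns=TIDY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tidy(path: str | Path) -> list:
    """Read a tidy TSV written by :func:`write_tidy` back into
    :class:`~arqiv.normalization.SubjectTimeCourse` objects."""
    from .normalization import SubjectTimeCourse, TimeCoursePoint

    df = pd.read_csv(path, sep="\t", dtype={"flags": str, "condition": str})
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"tidy file missing column(s): {', '.join(missing)}")
    out: dict[tuple, SubjectTimeCourse] = {}
    for _, row in df.iterrows():
        key = (row["subject_id"], row["channel"])
        cond = row["condition"]
        cond = None if (pd.isna(cond) or cond == "") else str(cond)
        tc = out.setdefault(
            key,
            SubjectTimeCourse(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                channel=str(row["channel"]),
                condition=cond,
            ),
        )
        flags = row["flags"]
        flags = () if (pd.isna(flags) or flags == "") else tuple(str(flags).split(";"))

        def _optional(x):
            return None if pd.isna(x) else float(x)

        tc.points.append(
            TimeCoursePoint(
                session_id=str(row["session_id"]),
                timepoint_hpf=float(row["timepoint_hpf"]),
                total_signal=float(row["total_signal_rfu"]),
                n_signal_regions=int(row["n_signal_regions"]),
                method=str(row["method"]),
                normalized_pct=_optional(row["normalized_pct"]),
                corrected_pct=_optional(row["corrected_pct"]),
                flags=flags,
            )
        )
    for tc in out.values():
        tc.points.sort(key=lambda p: p.timepoint_hpf)
    return list(out.values())
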