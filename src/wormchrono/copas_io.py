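"""Reading and writing COPAS-style event and profile tables.

The COPAS Biosort exports one delimited-text row per detected object with
its time of flight (TOF, a proxy for axial length), extinction (EXT,
integrated optical density) and green peak height; the profiler add-on
additionally records a longitudinal green-fluorescence trace per object.
Export dialects vary across instrument software versions, so the reader is
permissive (tab or comma separators, case-insensitive column aliases) while
every writer emits one canonical dialect: UTF-8, tab-separated, header row,
'.' decimal, ``NA`` missing token. Floats are written with ``repr`` so that
read(write(x)) is bit-exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, NamedTuple, Sequence, Union

import numpy as np

Source = Union[str, Path, IO[str]]


class FormatError(ValueError):
    """A table is structurally unusable (e.g. a mandatory column is absent)."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DuplicateIdError(ValueError):
    """An event identifier occurs more than once within one dataset."""

    def __init__(self, event_id: str):
        super().__init__(f"duplicate event_id {event_id!r}")
        self.event_id = event_id


@dataclass(frozen=True)
class EventRecord:
    """One detected object: axial-length proxy, optical density, green peak."""

    event_id: str
    tof: float
    ext: float
    ph_green: float

    def __post_init__(self):
        for name in ("tof", "ext", "ph_green"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class ProfileRecord:
    """Ordered longitudinal green-fluorescence samples for one event.

    The sample count is the "length" used throughout the pipeline.
    """

    event_id: str
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("profile needs at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("profile samples must be finite")

    def __len__(self) -> int:
        return int(self.samples.size)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProfileRecord)
            and self.event_id == other.event_id
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class PopulationDataset:
    """Joined events + profiles for one population under one condition."""

    condition_label: str
    events: list[EventRecord]
    profiles: dict[str, ProfileRecord]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.event_id for e in self.events]
        if len(ids) != len(set(ids)):
            seen = set()
            for i in ids:
                if i in seen:
                    raise DuplicateIdError(i)
                seen.add(i)
        missing = set(self.profiles) - set(ids)
        if missing:
            raise ValueError(f"profiles without matching event: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PopulationDataset)
            and self.condition_label == other.condition_label
            and self.events == other.events
            and self.profiles == other.profiles
            and self.metadata == other.metadata
        )

    def subset(self, event_ids: Iterable[str]) -> "PopulationDataset":
        keep = set(event_ids)
        return PopulationDataset(
            condition_label=self.condition_label,
            events=[e for e in self.events if e.event_id in keep],
            profiles={k: v for k, v in self.profiles.items() if k in keep},
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class Dialect:
    """Options of a delimited-text dialect; ``sep=None`` sniffs tab vs comma."""

    sep: str | None = "\t"
    na_token: str = "NA"

    #: case-insensitive header aliases, canonical field -> accepted names
    aliases: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("event_id", ("event_id", "id", "object", "worm", "sorter_id")),
        ("tof", ("tof", "time_of_flight")),
        ("ext", ("ext", "extinction")),
        ("ph_green", ("ph_green", "phgreen", "ph.green", "green", "peak_height_green")),
    )


CANONICAL = Dialect()
PERMISSIVE = Dialect(sep=None)


def _open(source: Source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _sniff_sep(header: str, dialect: Dialect) -> str:
    if dialect.sep is not None:
        return dialect.sep
    return "\t" if "\t" in header else ","


def _float(token: str, column: str, line_number: int) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ParseError(f"non-numeric value {token!r} in column {column!r}", line_number)
    if not math.isfinite(v):
        raise ParseError(f"non-finite value {token!r} in column {column!r}", line_number)
    return v


def read_event_table(source: Source, dialect: Dialect = PERMISSIVE) -> list[EventRecord]:
    """Parse one EventRecord per data row, preserving row order.

    Raises :class:`FormatError` naming any missing mandatory column and
    :class:`ParseError` with the file line number for malformed cells.
    """
    fh, close = _open(source)
    try:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError("empty table: no header row")
        sep = _sniff_sep(header_line, dialect)
        header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
        lower = [h.lower() for h in header]
        colmap: dict[str, int] = {}
        for canonical, names in dialect.aliases:
            for name in names:
                if name in lower:
                    colmap[canonical] = lower.index(name)
                    break
        for canonical, display in (("event_id", "id"), ("tof", "TOF"),
                                   ("ext", "EXT"), ("ph_green", "green")):
            if canonical not in colmap:
                raise FormatError(f"mandatory column {display!r} not found in header {header}")

        records: list[EventRecord] = []
        for line_number, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(sep)
            if len(cells) <= max(colmap.values()):
                raise ParseError(f"row has {len(cells)} cells, expected >= {max(colmap.values()) + 1}",
                                 line_number)
            records.append(EventRecord(
                event_id=cells[colmap["event_id"]].strip(),
                tof=_float(cells[colmap["tof"]], "TOF", line_number),
                ext=_float(cells[colmap["ext"]], "EXT", line_number),
                ph_green=_float(cells[colmap["ph_green"]], "green", line_number),
            ))
        return records
    finally:
        if close:
            fh.close()


class RejectedRow(NamedTuple):
    line_number: int
    event_id: str
    reason: str


class ProfileTableResult(NamedTuple):
    records: list[ProfileRecord]
    rejected: list[RejectedRow]


def read_profile_table(source: Source, dialect: Dialect = PERMISSIVE) -> ProfileTableResult:
    """Parse ragged profile rows: an event_id followed by its ordered samples.

    Rows with an empty sample list are not silently dropped — they are
    returned in ``rejected`` with a diagnostic, so that
    rows_in == len(records) + len(rejected).
    """
    fh, close = _open(source)
    records: list[ProfileRecord] = []
    rejected: list[RejectedRow] = []
    try:
        first = fh.readline()
        if not first:
            return ProfileTableResult(records, rejected)
        sep = _sniff_sep(first, dialect)
        lines = [(1, first)] + [(n, l) for n, l in enumerate(fh, start=2)]
        # optional header: first row whose second cell is not numeric
        start = 0
        cells = lines[0][1].rstrip("\n").split(sep)
        if len(cells) >= 2:
            try:
                float(cells[1])
            except ValueError:
                start = 1
        for line_number, line in lines[start:]:
            if not line.strip():
                continue
            cells = [c for c in line.rstrip("\n").split(sep) if c != ""]
            event_id = cells[0].strip()
            if len(cells) < 2:
                rejected.append(RejectedRow(line_number, event_id, "empty sample list"))
                continue
            samples = np.array([_float(c, "profile", line_number) for c in cells[1:]])
            if np.any(samples < 0):
                raise ParseError("negative profile sample", line_number)
            records.append(ProfileRecord(event_id=event_id, samples=samples))
        return ProfileTableResult(records, rejected)
    finally:
        if close:
            fh.close()


class JoinReport(NamedTuple):
    unmatched_events: list[str]
    unmatched_profiles: list[str]


def join_events_profiles(
    events: Sequence[EventRecord],
    profiles: Sequence[ProfileRecord],
    condition_label: str = "",
    metadata: dict[str, str] | None = None,
) -> tuple[PopulationDataset, JoinReport]:
    """Join on event_id, keeping only events that have a profile.

    The pipeline is profile-centric: events without a profile go to the
    unmatched report, not the dataset. Duplicate ids on either side raise
    :class:`DuplicateIdError`.
    """
    for seq in (events, profiles):
        seen: set[str] = set()
        for r in seq:
            if r.event_id in seen:
                raise DuplicateIdError(r.event_id)
            seen.add(r.event_id)
    prof_by_id = {p.event_id: p for p in profiles}
    event_ids = {e.event_id for e in events}
    kept = [e for e in events if e.event_id in prof_by_id]
    report = JoinReport(
        unmatched_events=[e.event_id for e in events if e.event_id not in prof_by_id],
        unmatched_profiles=[p.event_id for p in profiles if p.event_id not in event_ids],
    )
    dataset = PopulationDataset(
        condition_label=condition_label,
        events=kept,
        profiles={e.event_id: prof_by_id[e.event_id] for e in kept},
        metadata=dict(metadata or {}),
    )
    return dataset, report


# ---------------------------------------------------------------------------
# population round trip

_EVENT_HEADER = ["event_id", "TOF", "EXT", "PH.Green"]


def write_event_table(events: Sequence[EventRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EVENT_HEADER) + "\n")
        for e in events:
            fh.write(f"{e.event_id}\t{e.tof!r}\t{e.ext!r}\t{e.ph_green!r}\n")


def write_profile_table(profiles: Iterable[ProfileRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in profiles:
            fh.write(p.event_id + "\t" + "\t".join(repr(float(s)) for s in p.samples) + "\n")


def write_population(dataset: PopulationDataset, directory: str | Path) -> None:
    """Write events.tsv + profiles.tsv + meta.json (+ joined population.tsv)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_event_table(dataset.events, d / "events.tsv")
    write_profile_table(
        (dataset.profiles[e.event_id] for e in dataset.events if e.event_id in dataset.profiles),
        d / "profiles.tsv",
    )
    meta = {"condition_label": dataset.condition_label, "metadata": dataset.metadata}
    (d / "meta.json").write_text(
        json.dumps(meta, indent=2, ensure_ascii=False, sort_keys=True) + "\n", encoding="utf-8"
    )
    # single-file convenience view (not read back)
    with open(d / "population.tsv", "w", encoding="utf-8") as fh:
        fh.write("event_id\tTOF\tEXT\tPH.Green\tn_samples\tsamples\n")
        for e in dataset.events:
            p = dataset.profiles.get(e.event_id)
            samples = " ".join(repr(float(s)) for s in p.samples) if p else "NA"
            n = len(p) if p else 0
            fh.write(f"{e.event_id}\t{e.tof!r}\t{e.ext!r}\t{e.ph_green!r}\t{n}\t{samples}\n")


def read_population(directory: str | Path) -> PopulationDataset:
    d = Path(directory)
    events = read_event_table(d / "events.tsv", CANONICAL)
    profiles, rejected = read_profile_table(d / "profiles.tsv", CANONICAL)
    if rejected:
        raise FormatError(f"profiles.tsv contains {len(rejected)} malformed rows")
    meta = json.loads((d / "meta.json").read_text(encoding="utf-8"))
    dataset, report = join_events_profiles(
        events, profiles, condition_label=meta["condition_label"], metadata=meta["metadata"]
    )
    if report.unmatched_events or report.unmatched_profiles:
        raise FormatError(f"events.tsv and profiles.tsv disagree on ids: {report}")
    return dataset


# ---------------------------------------------------------------------------
# chronogram matrix

def write_chronogram_matrix(chronogram, path: str | Path, na_token: str = "NA") -> None:
    """One comma-separated row per retained length, shortest first; the ragged
    right edge is padded with an explicit NA token. A side-car row-metadata
    table (length, n_merged) is written next to it."""
    path = Path(path)
    rows = chronogram.rows
    width = max((r.length for r in rows), default=0)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(f"pos{i}" for i in range(width)) + "\n")
        for row in rows:
            cells = [repr(float(v)) for v in row.mean_profile]
            cells += [na_token] * (width - row.length)
            fh.write(",".join(cells) + "\n")
    sidecar = path.with_name(path.stem + "_rows.tsv")
    with open(sidecar, "w", encoding="utf-8") as fh:
        fh.write("length\tn_merged\n")
        for row in rows:
            fh.write(f"{row.length}\t{row.n_merged}\n")


def read_chronogram_matrix(path: str | Path, na_token: str = "NA"):
    """Inverse of :func:`write_chronogram_matrix` (provenance is not restored)."""
    from .pipeline import Chronogram, ChronogramRow

    path = Path(path)
    sidecar = path.with_name(path.stem + "_rows.tsv")
    meta: list[tuple[int, int]] = []
    with open(sidecar, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            if line.strip():
                length, n = line.split("\t")
                meta.append((int(length), int(n)))
    rows: list[ChronogramRow] = []
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)
        for (length, n_merged), line in zip(meta, fh):
            cells = line.rstrip("\n").split(",")
            values = np.array([float(c) for c in cells[:length]])
            rows.append(ChronogramRow(length=length, n_merged=n_merged, mean_profile=values))
    observed = {r.length for r in rows}
    skipped = [L for L in range(min(observed), max(observed) + 1) if L not in observed] if rows else []
    return Chronogram(rows=rows, skipped_lengths=skipped, provenance={"source": str(path)})
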