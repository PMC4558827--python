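"""Label-track I/O and annotation bookkeeping.

Annotations travel as tab-separated label-track files (the Audacity dialect):
one row per event, ``start<TAB>end<TAB>label`` with times in seconds written
to three decimals.  Session-level bookkeeping (per call-type counts, session
totals) lives in :class:`CallTypeSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .types import EventAnnotation


def read_label_track(path: str | Path) -> list[EventAnnotation]:
    """Parse a TSV label track; malformed rows are rejected with their line number."""
    events: list[EventAnnotation] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected start<TAB>end<TAB>label, got {raw!r}")
        try:
            start = float(parts[0])
            end = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric time field: {exc}") from None
        label = parts[2].strip()
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
        if not label:
            raise ValueError(f"{path}:{lineno}: empty label")
        events.append(EventAnnotation(start, end, label))
    return events


def write_label_track(events: list[EventAnnotation], path: str | Path) -> None:
    """Write events as a TSV label track, times to 3 decimals."""
    lines = [f"{e.start:.3f}\t{e.end:.3f}\t{e.label}" for e in events]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class AnnotationTable:
    """(session id, annotation) records across recording sessions."""

    records: list[tuple[str, EventAnnotation]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for session, _ in self.records:
            if not session:
                raise ValueError("session ids must be non-empty strings")

    def filter(self, label: str | None = None, session: str | None = None) -> "AnnotationTable":
        return AnnotationTable(
            [
                (s, a)
                for s, a in self.records
                if (label is None or a.label == label)
                and (session is None or s == session)
            ]
        )

    def sorted(self) -> "AnnotationTable":
        return AnnotationTable(sorted(self.records, key=lambda r: (r[0], r[1].start)))


@dataclass
class CallTypeSummary:
    """Counts per (session, call type) with session and grand totals."""

    counts: dict[str, dict[str, int]]  # session -> call type -> count

    def session_total(self, session: str) -> int:
        return sum(self.counts.get(session, {}).values())

    @property
    def grand_total(self) -> int:
        return sum(self.session_total(s) for s in self.counts)

    def call_type_total(self, call_type: str) -> int:
        return sum(c.get(call_type, 0) for c in self.counts.values())

    @property
    def sessions(self) -> list[str]:
        return sorted(self.counts)


def summarize_annotations(table: AnnotationTable) -> CallTypeSummary:
    """Tabulate annotation counts per (session, call type)."""
    counts: dict[str, dict[str, int]] = {}
    for session, ann in table.records:
        per = counts.setdefault(session, {})
        per[ann.label] = per.get(ann.label, 0) + 1
    return CallTypeSummary(counts)


def load_field_call_counts() -> CallTypeSummary:
    """Call counts from the 2011/2012 field sessions at Bela Bela and Addo.

    Read from the packaged TSV (session, call_type, count per row).
    """
    text = resources.files("elemon.data").joinpath("field_call_counts.tsv").read_text()
    counts: dict[str, dict[str, int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#") or lineno == 1:
            continue
        session, call_type, n = raw.split("\t")
        counts.setdefault(session, {})[call_type] = int(n)
    return CallTypeSummary(counts)


def expand_counts_to_table(
    summary: CallTypeSummary, spacing: float = 10.0, duration: float = 2.0
) -> AnnotationTable:
    """Materialise a summary as an AnnotationTable with synthetic placeholder times.

    Only the (session, label) multiplicities are meaningful; intervals are
    laid out on a regular grid so the records satisfy the annotation
    invariants.
    """
    records: list[tuple[str, EventAnnotation]] = []
    for session in summary.sessions:
        t = 0.0
        for call_type in sorted(summary.counts[session]):
            for _ in range(summary.counts[session][call_type]):
                records.append((session, EventAnnotation(t, t + duration, call_type)))
                t += spacing
    return AnnotationTable(records)
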