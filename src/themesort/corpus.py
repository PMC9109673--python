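"""Data model and CSV I/O for quote corpora and rater sort tables.

The study design this package serves: a fixed set of N numbered qualitative
quotes is sorted independently by R raters ("co-researchers"), each rater
partitioning the quotes into self-defined labelled groups. Sorts are
exchanged as long-format CSV with one row per (quote, rater, group)
assignment — the three-column Topic / Person / Group layout used when the
sorts are collated in a spreadsheet.

Canonical headers are ``quote_id,rater_id,group_label`` for sort tables and
``quote_id,text,source_tag`` for corpora; common aliases (topic, person,
group, ...) are recognised automatically and custom ones can be supplied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DuplicateAssignmentError,
    FormatError,
    ParseError,
)

#: Default header aliases, lower-cased. Keys are canonical column names.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "quote_id": ("quote_id", "topic", "excerpt id", "excerpt_id", "quote"),
    "rater_id": ("rater_id", "person", "co-researcher id", "co_researcher_id", "rater"),
    "group_label": ("group_label", "group", "theme", "grp"),
}


@dataclass(frozen=True)
class Quote:
    """One numbered quote (a node of the co-occurrence network)."""

    quote_id: int
    text: str = ""
    source_tag: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.quote_id, int) or self.quote_id < 1:
            raise ParseError(f"quote_id must be a positive integer, got {self.quote_id!r}")


@dataclass
class QuoteCorpus:
    """Ordered collection of quotes with unique 1-based integer ids."""

    quotes: list[Quote]

    def __post_init__(self) -> None:
        ids = [q.quote_id for q in self.quotes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate quote ids in corpus: {dupes}")

    @property
    def n_quotes(self) -> int:
        return len(self.quotes)

    @property
    def quote_ids(self) -> list[int]:
        return [q.quote_id for q in self.quotes]

    def __contains__(self, quote_id: int) -> bool:
        return quote_id in set(self.quote_ids)

    @classmethod
    def from_ids(cls, ids: Iterable[int]) -> "QuoteCorpus":
        """Corpus of placeholder quotes — used when only ids matter."""
        return cls([Quote(i, text=f"Quote {i}") for i in ids])


@dataclass
class RaterSort:
    """One rater's partition of quote ids into labelled groups.

    ``assignment`` maps quote_id -> group label. Group labels are scoped to
    the rater: "Grp1" from two different raters are unrelated groups.
    """

    rater_id: str
    assignment: dict[int, str]

    def __post_init__(self) -> None:
        if not str(self.rater_id):
            raise FormatError("rater_id must be non-empty")
        for q, g in self.assignment.items():
            if not isinstance(q, int) or q < 1:
                raise ParseError(f"quote id must be a positive integer, got {q!r}")
            if g == "":
                raise FormatError(f"empty group label for quote {q} (rater {self.rater_id})")

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def groups(self) -> dict[str, set[int]]:
        """Group label -> set of quote ids."""
        out: dict[str, set[int]] = {}
        for q, g in self.assignment.items():
            out.setdefault(g, set()).add(q)
        return out

    def covered(self) -> set[int]:
        return set(self.assignment)


@dataclass
class SortStudy:
    """A corpus plus the collection of rater sorts over it."""

    corpus: QuoteCorpus
    sorts: list[RaterSort]

    def __post_init__(self) -> None:
        rater_ids = [s.rater_id for s in self.sorts]
        if len(rater_ids) != len(set(rater_ids)):
            raise FormatError("rater ids must be distinct within a study")

    @property
    def n_raters(self) -> int:
        return len(self.sorts)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is 'error' or 'warning'."""

    level: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.message}"


def _resolve_columns(
    header: Sequence[str], aliases: Mapping[str, Sequence[str]]
) -> dict[str, str]:
    """Map canonical column names onto actual header names, or raise."""
    lowered = {h.lower().strip(): h for h in header}
    resolved: dict[str, str] = {}
    for canonical, names in aliases.items():
        for name in names:
            if name.lower() in lowered:
                resolved[canonical] = lowered[name.lower()]
                break
        else:
            raise FormatError(
                f"missing required column {canonical!r} "
                f"(accepted aliases: {', '.join(names)}; header was {list(header)})"
            )
    return resolved


def read_sort_table(
    path: str | Path,
    aliases: Mapping[str, Sequence[str]] | None = None,
) -> list[RaterSort]:
    """Read a long-format sort table into one :class:`RaterSort` per rater.

    Raises :class:`FormatError` for a missing column,
    :class:`DuplicateAssignmentError` (citing the row number) when the same
    (quote, rater) pair carries two different groups, and
    :class:`ParseError` for a non-integer quote id. Group labels are kept
    verbatim as strings. Rater order follows first appearance.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_columns(frame.columns, aliases or COLUMN_ALIASES)

    sorts: dict[str, dict[int, str]] = {}
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        # positional access avoids attribute names mangled by pandas
        qraw = row[frame.columns.get_loc(cols["quote_id"])]
        rater = str(row[frame.columns.get_loc(cols["rater_id"])])
        group = str(row[frame.columns.get_loc(cols["group_label"])])
        try:
            qid = int(str(qraw).strip())
        except ValueError:
            raise ParseError(
                f"row {row_no}: quote id {qraw!r} is not an integer"
            ) from None
        if qid < 1:
            raise ParseError(f"row {row_no}: quote id must be >= 1, got {qid}")
        if rater == "":
            raise FormatError(f"row {row_no}: empty rater id")
        if group == "":
            raise FormatError(f"row {row_no}: empty group label")
        bucket = sorts.setdefault(rater, {})
        if qid in bucket and bucket[qid] != group:
            raise DuplicateAssignmentError(
                f"row {row_no}: quote {qid} already assigned to group "
                f"{bucket[qid]!r} for rater {rater!r}, now {group!r}"
            )
        bucket[qid] = group
    return [RaterSort(rater_id=r, assignment=a) for r, a in sorts.items()]


def write_sort_table(sorts: Iterable[RaterSort], path: str | Path) -> None:
    """Write sorts as canonical CSV; inverse of :func:`read_sort_table`.

    Rows are emitted rater by rater (input order), quotes ascending, so
    output is deterministic for a given input.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["quote_id", "rater_id", "group_label"])
        for sort in sorts:
            for qid in sorted(sort.assignment):
                writer.writerow([qid, sort.rater_id, sort.assignment[qid]])


def read_corpus(path: str | Path) -> QuoteCorpus:
    """Read a quote corpus CSV (``quote_id,text[,source_tag]``)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {c.lower().strip(): c for c in frame.columns}
    if "quote_id" not in cols or "text" not in cols:
        raise FormatError(
            f"corpus needs columns quote_id,text; header was {list(frame.columns)}"
        )
    quotes = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        qraw = row[frame.columns.get_loc(cols["quote_id"])]
        try:
            qid = int(str(qraw).strip())
        except ValueError:
            raise ParseError(f"row {row_no}: quote id {qraw!r} is not an integer") from None
        text = str(row[frame.columns.get_loc(cols["text"])])
        tag = None
        if "source_tag" in cols:
            tag = str(row[frame.columns.get_loc(cols["source_tag"])]) or None
        quotes.append(Quote(qid, text=text, source_tag=tag))
    return QuoteCorpus(quotes)


def write_corpus(corpus: QuoteCorpus, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["quote_id", "text", "source_tag"])
        for q in corpus.quotes:
            writer.writerow([q.quote_id, q.text, q.source_tag or ""])


def validate_study(study: SortStudy, require_complete: bool = False) -> list[Finding]:
    """Enumerate inconsistencies between a corpus and its sorts.

    Findings cover: quote ids referenced by a sort but absent from the
    corpus (always errors) and corpus quotes a rater left unassigned
    (warnings, or errors when ``require_complete``). An empty report means
    the study is internally consistent.
    """
    findings: list[Finding] = []
    corpus_ids = set(study.corpus.quote_ids)
    level = "error" if require_complete else "warning"
    for sort in study.sorts:
        unknown = sorted(sort.covered() - corpus_ids)
        for qid in unknown:
            findings.append(
                Finding("error", f"rater {sort.rater_id!r} references unknown quote id {qid}")
            )
        missing = sorted(corpus_ids - sort.covered())
        for qid in missing:
            findings.append(
                Finding(level, f"rater {sort.rater_id!r} left quote {qid} unassigned")
            )
    return findings
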