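"""Agreement between consensus themes and an independent coder's grouping.

Validation of a consensus theme set asks how closely an analyst who
re-grouped the same quotes, blind to the consensus labels, agrees with it.
Because the two groupings use unrelated labels, they are first aligned:
each consensus theme is matched to at most one coder group (an injective
mapping) so that the total number of quotes falling on the matched
diagonal is maximal — a rectangular assignment problem solved exactly.
From the aligned contingency table the report gives overall percent
agreement, per-theme percent agreement, and the label-free chance-corrected
statistics ARI and NMI.

The injective restriction matters: when the coder splits one theme into
two groups, only one of them can be credited, so the split shows up as a
low per-theme percentage instead of being hidden by double-counting.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .corpus import RaterSort
from .consensus import ThemeSet
from .errors import CoverageError, EmptyOverlapError


@dataclass
class ContingencyTable:
    """K x L cross-tabulation of theme vs coder-group membership."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # shape (K, L), non-negative ints
    reference_only: list[int] = field(default_factory=list)
    coder_only: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow([""] + self.col_labels)
            for label, row in zip(self.row_labels, self.counts):
                writer.writerow([label] + [int(x) for x in row])


def contingency_table(reference: ThemeSet, coder: RaterSort) -> ContingencyTable:
    """Cross-tabulate quotes over (consensus theme, coder group).

    Quotes covered by only one side are excluded from the counts but
    listed in the table so they are never silently dropped. Row order
    follows the reference theme order; columns are sorted coder labels.
    """
    ref_assignment = reference.assignment
    coder_assignment = coder.assignment
    common = set(ref_assignment) & set(coder_assignment)
    if not common:
        raise EmptyOverlapError("reference and coder cover no common quotes")
    row_labels = list(reference.themes)
    col_labels = sorted(coder.groups)
    row_index = {lab: i for i, lab in enumerate(row_labels)}
    col_index = {lab: j for j, lab in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for q in common:
        counts[row_index[ref_assignment[q]], col_index[coder_assignment[q]]] += 1
    return ContingencyTable(
        row_labels=row_labels,
        col_labels=col_labels,
        counts=counts,
        reference_only=sorted(set(ref_assignment) - common),
        coder_only=sorted(set(coder_assignment) - common),
    )


def align_partitions(table: ContingencyTable) -> dict[str, str | None]:
    """Injective theme -> coder-group mapping maximising matched quotes.

    Solved exactly as a rectangular assignment; when there are more themes
    than coder groups, the surplus themes stay unmapped (value ``None``).
    Among the maximisers, the mapping that is lexicographically smallest in
    theme order (by coder-group column index, unmapped sorting last) is
    returned, so the result is deterministic.
    """
    counts = table.counts
    k, l = counts.shape

    def best_total(fixed: dict[int, int]) -> int:
        """Optimal matched total with some rows pre-assigned to columns."""
        free_rows = [r for r in range(k) if r not in fixed]
        free_cols = [c for c in range(l) if c not in fixed.values()]
        total = sum(counts[r, c] for r, c in fixed.items())
        if free_rows and free_cols:
            sub = counts[np.ix_(free_rows, free_cols)]
            ri, ci = linear_sum_assignment(sub, maximize=True)
            total += int(sub[ri, ci].sum())
        return int(total)

    optimum = best_total({})
    fixed: dict[int, int] = {}
    n_mapped = min(k, l)
    for r in range(k):
        if len(fixed) == n_mapped:
            break
        # try columns in ascending index; falling through means r stays unmapped
        for c in range(l):
            if c in fixed.values():
                continue
            trial = dict(fixed)
            trial[r] = c
            # r can only stay unmapped if enough rows remain to fill all slots
            if best_total(trial) == optimum:
                fixed[r] = c
                break
        else:
            if k - r - 1 < n_mapped - len(fixed):
                raise AssertionError("assignment bookkeeping failed")  # pragma: no cover
    mapping: dict[str, str | None] = {}
    for r, label in enumerate(table.row_labels):
        mapping[label] = table.col_labels[fixed[r]] if r in fixed else None
    return mapping


def exhaustive_align_total(counts: np.ndarray) -> int:
    """Brute-force optimum over all injective row->column mappings.

    Independent oracle for :func:`align_partitions`; factorial cost, only
    for small tables.
    """
    from itertools import combinations

    k, l = counts.shape
    best = 0
    n_mapped = min(k, l)
    for chosen in combinations(range(k), n_mapped):
        for cols in permutations(range(l), n_mapped):
            total = sum(counts[r, c] for r, c in zip(chosen, cols))
            best = max(best, total)
    return int(best)


def _partition_arrays(
    p1: Mapping[int, object], p2: Mapping[int, object]
) -> tuple[list, list]:
    if set(p1) != set(p2):
        missing = sorted(set(p1) ^ set(p2))
        raise CoverageError(f"partitions cover different quote sets (diff: {missing[:10]})")
    keys = sorted(p1)
    return [p1[q] for q in keys], [p2[q] for q in keys]


def adjusted_rand_index(p1: Mapping[int, object], p2: Mapping[int, object]) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    a, b = _partition_arrays(p1, p2)
    return float(adjusted_rand_score(a, b))


def normalized_mutual_information(
    p1: Mapping[int, object], p2: Mapping[int, object]
) -> float:
    """NMI with arithmetic-mean normalisation."""
    a, b = _partition_arrays(p1, p2)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


@dataclass
class AgreementReport:
    """Alignment plus overall/per-theme agreement and chance-corrected stats."""

    table: ContingencyTable
    mapping: dict[str, str | None]
    overall_percent: float
    per_theme_percent: dict[str, float]
    ari: float
    nmi: float
    unmapped_themes: list[str]
    denominator: str = "theme"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "overall_percent": self.overall_percent,
            "per_theme_percent": self.per_theme_percent,
            "ari": self.ari,
            "nmi": self.nmi,
            "mapping": self.mapping,
            "unmapped_themes": self.unmapped_themes,
            "denominator": self.denominator,
            "n_common": self.table.n,
            "reference_only": self.table.reference_only,
            "coder_only": self.table.coder_only,
            "contingency": {
                "rows": self.table.row_labels,
                "cols": self.table.col_labels,
                "counts": self.table.counts.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    def render(self) -> str:
        """Human-readable summary; percentages to one decimal."""
        lines = [
            f"Quotes compared: {self.table.n}",
            f"Overall agreement: {self.overall_percent:.1f}%",
            f"ARI: {self.ari:.3f}    NMI: {self.nmi:.3f}",
            "Per-theme agreement:",
        ]
        for label in self.table.row_labels:
            target = self.mapping[label]
            arrow = f"-> {target}" if target is not None else "(unmapped)"
            lines.append(
                f"  {label} {arrow}: {self.per_theme_percent[label]:.1f}%"
            )
        if self.table.reference_only:
            lines.append(f"Reference-only quotes: {self.table.reference_only}")
        if self.table.coder_only:
            lines.append(f"Coder-only quotes: {self.table.coder_only}")
        return "\n".join(lines)


def agreement_report(
    reference: ThemeSet,
    coder: RaterSort,
    denominator: str = "theme",
) -> AgreementReport:
    """Full agreement report between consensus themes and a coder's sort.

    ``denominator`` selects the per-theme base: "theme" (consensus theme
    size — the default reading of per-theme similarity) or "coder"
    (matched coder group size, for sensitivity analysis). Overall percent
    always uses all jointly covered quotes.
    """
    if denominator not in ("theme", "coder"):
        raise ValueError(f"denominator must be 'theme' or 'coder', got {denominator!r}")
    table = contingency_table(reference, coder)
    mapping = align_partitions(table)
    row_index = {lab: i for i, lab in enumerate(table.row_labels)}
    col_index = {lab: j for j, lab in enumerate(table.col_labels)}
    matched = 0
    per_theme: dict[str, float] = {}
    for label in table.row_labels:
        target = mapping[label]
        r = row_index[label]
        if target is None:
            per_theme[label] = 0.0
            continue
        n_match = int(table.counts[r, col_index[target]])
        matched += n_match
        base = (
            int(table.row_sums[r])
            if denominator == "theme"
            else int(table.col_sums[col_index[target]])
        )
        per_theme[label] = 100.0 * n_match / base if base else 0.0
    ref_common = {
        q: lab for q, lab in reference.assignment.items() if q in coder.assignment
    }
    coder_common = {q: g for q, g in coder.assignment.items() if q in ref_common}
    return AgreementReport(
        table=table,
        mapping=mapping,
        overall_percent=100.0 * matched / table.n,
        per_theme_percent=per_theme,
        ari=adjusted_rand_index(ref_common, coder_common),
        nmi=normalized_mutual_information(ref_common, coder_common),
        unmapped_themes=[lab for lab, tgt in mapping.items() if tgt is None],
        denominator=denominator,
    )
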