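"""Variant expression via smallest-covering-exon read counts.

A variant's expression signal is the read count of the smallest exon covering
its position (mirroring a counting workflow that builds a feature file from
the smallest exons covering the target variants).  A variant covered by no
exon, or whose exon has zero reads, is treated as not detectably expressed —
which conflates true silence with poor bait performance, a documented caveat.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .regions import Interval
from .truth import VariantKey

__all__ = [
    "ExonRecord",
    "ExonIndex",
    "read_exon_table",
    "write_exon_table",
    "read_exons_gff3",
    "smallest_covering_exon",
    "variant_expression",
    "expression_contrast",
]


@dataclass(frozen=True)
class ExonRecord:
    exon_id: str
    interval: Interval
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")


class ExonIndex:
    """Point-stabbing index over exons for repeated variant lookups."""

    def __init__(self, exons: list[ExonRecord]):
        self.exons = list(exons)
        self._trees: dict[str, IntervalTree] = {}
        for ex in self.exons:
            tree = self._trees.setdefault(ex.interval.chrom, IntervalTree())
            tree.addi(ex.interval.start, ex.interval.end, ex)

    def smallest_covering(self, key: VariantKey) -> ExonRecord | None:
        """The smallest exon containing the variant's 0-based anchor base.

        Ties on length break by smaller start, then lexicographic exon_id;
        ``None`` when no exon covers the position.
        """
        tree = self._trees.get(key.chrom)
        if tree is None:
            return None
        hits = [iv.data for iv in tree.at(key.pos - 1)]
        if not hits:
            return None
        return min(hits, key=lambda e: (e.interval.size, e.interval.start, e.exon_id))

    def expression(self, key: VariantKey) -> int:
        """Read count of the smallest covering exon; 0 when uncovered."""
        ex = self.smallest_covering(key)
        return ex.count if ex is not None else 0


def smallest_covering_exon(exons: list[ExonRecord], key: VariantKey) -> ExonRecord | None:
    return ExonIndex(exons).smallest_covering(key)


def variant_expression(exons: list[ExonRecord], key: VariantKey) -> int:
    return ExonIndex(exons).expression(key)


def expression_contrast(detected: list[int], missed: list[int]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of detected vs missed expression counts."""
    if not detected or not missed:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(detected, missed, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# I/O

_COLS = ["exon_id", "chrom", "start", "end", "count"]


def write_exon_table(exons: list[ExonRecord], path: str | Path) -> None:
    rows = [
        {
            "exon_id": e.exon_id,
            "chrom": e.interval.chrom,
            "start": e.interval.start,
            "end": e.interval.end,
            "count": e.count,
        }
        for e in exons
    ]
    pd.DataFrame(rows, columns=_COLS).to_csv(path, sep="\t", index=False)


def read_exon_table(path: str | Path) -> list[ExonRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ExonRecord(str(r.exon_id), Interval(r.chrom, int(r.start), int(r.end)), int(r.count))
        for r in df.itertuples(index=False)
    ]


def read_exons_gff3(path: str | Path, count_attr: str = "count") -> list[ExonRecord]:
    """Read exon features from a GFF3 file (1-based inclusive -> half-open).

    The read count is taken from the ``count_attr`` attribute when present,
    else 0; the exon id from ``ID`` or ``exon_id``.
    """
    out: list[ExonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2].lower() != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            exon_id = attrs.get("ID") or attrs.get("exon_id") or f"exon{lineno}"
            count = int(float(attrs.get(count_attr, 0)))
            out.append(
                ExonRecord(exon_id, Interval(fields[0], int(fields[3]) - 1, int(fields[4])), count)
            )
    return out
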