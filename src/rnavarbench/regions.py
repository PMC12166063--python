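"""Genomic interval sets and BED3 I/O.

Targeted panels and the high-confidence Consensus Target Region (CTR) are
represented as merged, sorted interval sets in BED convention (0-based,
half-open).  Every downstream analysis is restricted to the intersection of a
panel's target regions with the CTR, so the only operations needed are merge,
intersection, point membership and total size.

VCF coordinates are 1-based; the conversion to BED space happens exclusively
inside :meth:`RegionSet.contains` and the restriction helpers, never at call
sites.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = ["Interval", "RegionSet", "read_bed", "write_bed", "intersect"]


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def size(self) -> int:
        return self.end - self.start


def _merge_sorted(ivals: list[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals; input sorted by (chrom, start)."""
    merged: list[Interval] = []
    for iv in ivals:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class RegionSet:
    """A merged, sorted set of genomic intervals.

    Construction always sorts and merges, so adjacent/overlapping input
    intervals collapse and ``total_size`` counts each base once.
    """

    intervals: list[Interval] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.intervals = _merge_sorted(sorted(self.intervals))
        # per-chromosome start/end arrays for O(log n) membership tests
        self._index: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            starts, ends = self._index.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    @property
    def total_size(self) -> int:
        return sum(iv.size for iv in self.intervals)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._index)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position ``pos`` falls inside the set.

        ``pos`` follows VCF convention; the 0-based base is ``pos - 1``.
        """
        if pos < 1:
            raise ValueError(f"pos must be >= 1, got {pos}")
        entry = self._index.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        p = pos - 1
        i = bisect.bisect_right(starts, p) - 1
        return i >= 0 and p < ends[i]

    def contains_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`contains` for an array of 1-based positions."""
        entry = self._index.get(chrom)
        if entry is None:
            return np.zeros(len(pos), dtype=bool)
        starts = np.asarray(entry[0])
        ends = np.asarray(entry[1])
        p = np.asarray(pos, dtype=np.int64) - 1
        i = np.searchsorted(starts, p, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(p), dtype=bool)
        out[ok] = p[ok] < ends[i[ok]]
        return out

    def positions(self) -> Iterable[tuple[str, int]]:
        """Iterate every (chrom, 1-based pos) in the set. Use on small sets only."""
        for iv in self.intervals:
            for p0 in range(iv.start, iv.end):
                yield iv.chrom, p0 + 1


def intersect(a: RegionSet, b: RegionSet, label: str = "") -> RegionSet:
    """Base-wise intersection of two region sets (commutative, idempotent)."""
    out: list[Interval] = []
    for chrom in set(a._index) & set(b._index):
        sa, ea = a._index[chrom]
        sb, eb = b._index[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if lo < hi:
                out.append(Interval(chrom, lo, hi))
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return RegionSet(out, label=label or f"{a.label}&{b.label}")


def read_bed(path: str | Path, label: str = "") -> RegionSet:
    """Read a BED3+ file (tab-separated, no header) into a :class:`RegionSet`.

    Coordinates are BED 0-based half-open.  Malformed lines raise with the
    offending line number.
    """
    path = Path(path)
    ivals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}") from exc
            try:
                ivals.append(Interval(chrom, start, end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(ivals, label=label or path.stem)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3."""
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
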