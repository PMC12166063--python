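"""Reference-sample ground truth: known positives, known negatives, classification.

The reference sample (an equal-mass mixture of ten cancer cell lines) comes with
an established truth set: known-positive (KP) variants, each with a truth VAF,
and known-negative (KN) positions at which no variant exists, all valid inside a
high-confidence Consensus Target Region.  The truth set is *incomplete*: a call
at a position that is neither a KP key nor a KN position cannot be adjudicated
and is labelled UNCHARACTERIZED.

A KN position is negative for every alternative allele at that position, so any
non-KP call anchored there is a false positive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .regions import RegionSet, intersect

__all__ = [
    "VariantKey",
    "TruthSet",
    "ClassLabel",
    "restrict_truth",
    "read_truth_vcf",
    "write_truth_vcf",
    "read_kn_bed",
    "write_kn_bed",
]

#: Largest ref/alt length difference accepted (SNVs and small indels analysed together).
MAX_INDEL = 5


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalised variant identity: chrom, 1-based pos of first REF base, REF, ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom or not self.ref or not self.alt:
            raise ValueError("chrom, ref and alt must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def indel_size(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


class ClassLabel(enum.Enum):
    """Truth-based call class (exhaustive, mutually exclusive)."""

    KP = "KP"
    FP = "FP"
    UNCHARACTERIZED = "UNCHARACTERIZED"


class OutOfRegionError(ValueError):
    """A variant lies outside the truth set's region; restrict the call set first."""


@dataclass
class TruthSet:
    """Known positives, known negatives and the region they are valid in.

    ``kp`` maps each KP :class:`VariantKey` to its truth VAF (fraction).  ``kn``
    holds sorted arrays of 1-based KN positions, keyed by chromosome.
    """

    kp: dict[VariantKey, float] = field(default_factory=dict)
    kn: dict[str, np.ndarray] = field(default_factory=dict)
    region: RegionSet = field(default_factory=RegionSet)

    def __post_init__(self) -> None:
        self.kn = {c: np.unique(np.asarray(p, dtype=np.int64)) for c, p in self.kn.items()}
        kp_by_chrom: dict[str, list[int]] = {}
        for k in self.kp:
            kp_by_chrom.setdefault(k.chrom, []).append(k.pos)
        for c, arr in self.kn.items():
            loci = kp_by_chrom.get(c)
            if loci is not None and len(arr):
                clash = arr[np.isin(arr, np.asarray(loci, dtype=np.int64))]
                if len(clash):
                    raise ValueError(f"KN position {c}:{int(clash[0])} collides with a KP locus")

    @property
    def kn_size(self) -> int:
        """Number of KN positions (the FPR denominator before the 1e6 scaling)."""
        return sum(len(a) for a in self.kn.values())

    def is_kn(self, chrom: str, pos: int) -> bool:
        arr = self.kn.get(chrom)
        if arr is None or not len(arr):
            return False
        i = np.searchsorted(arr, pos)
        return i < len(arr) and arr[i] == pos

    def classify(self, key: VariantKey) -> ClassLabel:
        """Classify a call against the truth set.

        KP on an exact chrom/pos/ref/alt match; FP if the anchor position is a
        KN position; UNCHARACTERIZED otherwise.  Raises
        :class:`OutOfRegionError` for keys outside the truth region.
        """
        if not self.region.contains(key.chrom, key.pos):
            raise OutOfRegionError(
                f"{key.chrom}:{key.pos} outside truth region; restrict the call set first"
            )
        if key in self.kp:
            return ClassLabel.KP
        if self.is_kn(key.chrom, key.pos):
            return ClassLabel.FP
        return ClassLabel.UNCHARACTERIZED


def classify_call(t: TruthSet, key: VariantKey) -> ClassLabel:
    """Functional alias for :meth:`TruthSet.classify`."""
    return t.classify(key)


def restrict_truth(t: TruthSet, r: RegionSet) -> TruthSet:
    """Restrict KP, KN and the region itself to ``r`` (counts never increase)."""
    new_region = intersect(t.region, r)
    kp = {k: v for k, v in t.kp.items() if new_region.contains(k.chrom, k.pos)}
    kn = {}
    for chrom, arr in t.kn.items():
        mask = new_region.contains_many(chrom, arr)
        if mask.any():
            kn[chrom] = arr[mask]
    return TruthSet(kp=kp, kn=kn, region=new_region)


# ---------------------------------------------------------------------------
# I/O: KP truth as VCF with a truth-VAF INFO tag; KN as BED of single bases.


def _truth_header(contigs: list[str], tvaf_tag: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c, length=2**29)
    header.info.add(tvaf_tag, 1, "Float", "Truth variant allele fraction")
    return header


def write_truth_vcf(t: TruthSet, path: str | Path, tvaf_tag: str = "TVAF") -> None:
    header = _truth_header(sorted({k.chrom for k in t.kp}) or ["chr1"], tvaf_tag)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(t.kp):
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            rec.info[tvaf_tag] = float(t.kp[key])
            out.write(rec)


def read_truth_vcf(
    path: str | Path,
    kn: dict[str, np.ndarray] | None = None,
    region: RegionSet | None = None,
    tvaf_tag: str = "TVAF",
    max_indel: int = MAX_INDEL,
) -> TruthSet:
    """Read KP truth from a VCF; combine with KN positions and a region."""
    kp: dict[VariantKey, float] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                key = VariantKey(rec.contig, rec.pos, rec.ref.upper(), alt.upper())
                if key.indel_size > max_indel:
                    continue
                tvaf = rec.info.get(tvaf_tag)
                if isinstance(tvaf, tuple):
                    tvaf = tvaf[0]
                kp[key] = float(tvaf) if tvaf is not None else float("nan")
    return TruthSet(kp=kp, kn=kn or {}, region=region if region is not None else RegionSet())


def write_kn_bed(kn: dict[str, np.ndarray], path: str | Path) -> None:
    """Write KN positions as a BED of single-base intervals (pos-1, pos)."""
    frames = [
        pd.DataFrame({"chrom": chrom, "start": arr - 1, "end": arr})
        for chrom, arr in sorted(kn.items())
    ]
    df = pd.concat(frames) if frames else pd.DataFrame(columns=["chrom", "start", "end"])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_kn_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read single-base KN intervals back into per-chromosome 1-based arrays."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], dtype={0: str, 1: np.int64, 2: np.int64})
    except pd.errors.EmptyDataError:
        return {}
    if ((df["end"] - df["start"]) != 1).any():
        raise ValueError(f"{path}: KN BED must contain single-base intervals")
    return {
        str(chrom): np.unique(sub["end"].to_numpy(dtype=np.int64))
        for chrom, sub in df.groupby("chrom")
    }
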