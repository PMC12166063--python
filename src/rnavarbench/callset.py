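"""Per-caller VCF parsing and multi-caller call-set assembly.

Each variant caller contributes one VCF per library replicate.  Records are
normalised to one :class:`CallRecord` per alternative allele, then the callers'
lists are merged on variant identity: the caller membership set is the union
and the evidence triple (VAF, DP, ADP) is taken from the highest-priority
caller reporting the key, mirroring an ensemble pipeline that emits a single
consensus record per variant.

VAF is stored as a fraction throughout; it is rendered as a percentage only in
reports.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

from .regions import RegionSet
from .truth import MAX_INDEL, VariantKey

__all__ = [
    "Assay",
    "CallRecord",
    "CallSet",
    "read_caller_vcf",
    "merge_callers",
    "restrict_callset",
    "read_callset_tsv",
    "write_callset_tsv",
]

#: tolerance between a caller-reported VAF and ADP/DP
VAF_CONSISTENCY_TOL = 0.02


class Assay(enum.Enum):
    RNA = "RNA"
    DNA = "DNA"
    WTS = "WTS"


@dataclass(frozen=True)
class CallRecord:
    """One called variant with its supporting evidence.

    ``vaf`` is the variant allele fraction, ``dp`` the total read depth at the
    position and ``adp`` the alternative-allele read depth.  ``callers`` is the
    set of caller names that reported the key; ``flags`` carries provenance
    strings such as ``"clustered_events"``.
    """

    key: VariantKey
    vaf: float
    dp: int
    adp: int
    callers: frozenset[str]
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.dp < 0 or self.adp < 0:
            raise ValueError("dp and adp must be non-negative")
        if self.adp > self.dp:
            raise ValueError(f"adp ({self.adp}) exceeds dp ({self.dp})")
        if self.dp > 0 and abs(self.vaf - self.adp / self.dp) > VAF_CONSISTENCY_TOL:
            raise ValueError(
                f"vaf {self.vaf:.4f} inconsistent with adp/dp = "
                f"{self.adp}/{self.dp} at {self.key.chrom}:{self.key.pos}"
            )
        if not self.callers:
            raise ValueError("callers must be non-empty")


@dataclass
class CallSet:
    """All calls for one panel x replicate x assay, keyed by variant identity."""

    panel_id: str
    replicate_id: str
    assay: Assay
    records: dict[VariantKey, CallRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[VariantKey]:
        return set(self.records)

    def with_records(self, records: dict[VariantKey, CallRecord]) -> "CallSet":
        return CallSet(self.panel_id, self.replicate_id, self.assay, records)


def _record_from_vcf(rec, alt: str, alt_index: int, caller: str) -> CallRecord | None:
    """Extract (vaf, dp, adp) for one alt allele from FORMAT (first sample) or INFO."""
    dp = adp = af = None
    if rec.samples:
        sample = rec.samples[0]
        dp = sample.get("DP")
        ad = sample.get("AD")
        af = sample.get("AF")
        if ad is not None and len(ad) > alt_index + 1 and ad[alt_index + 1] is not None:
            adp = ad[alt_index + 1]
    if dp is None:
        dp = rec.info.get("DP")
    if adp is None:
        ad = rec.info.get("AD")
        if isinstance(ad, tuple) and len(ad) > alt_index + 1:
            adp = ad[alt_index + 1]
    if af is None:
        af = rec.info.get("AF")
    if isinstance(af, tuple):
        af = af[alt_index] if len(af) > alt_index else None

    if dp is None or (adp is None and af is None):
        return None
    dp = int(dp)
    if adp is None:
        adp = round(float(af) * dp)  # derived field: AD absent, AF + DP present
    adp = int(adp)
    vaf = float(af) if af is not None else (adp / dp if dp else 0.0)
    key = VariantKey(rec.contig, rec.pos, rec.ref.upper(), alt.upper())
    return CallRecord(key=key, vaf=vaf, dp=dp, adp=adp, callers=frozenset({caller}))


def read_caller_vcf(
    path: str | Path, caller: str, max_indel: int = MAX_INDEL
) -> list[CallRecord]:
    """Read one caller's VCF into normalised records (one per alt allele).

    Records missing depth evidence are skipped with a warning; indels larger
    than ``max_indel`` bases are dropped.
    """
    out: list[CallRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for i, alt in enumerate(rec.alts or ()):
                if abs(len(rec.ref) - len(alt)) > max_indel:
                    continue
                cr = _record_from_vcf(rec, alt, i, caller)
                if cr is None:
                    warnings.warn(
                        f"{path}: record {rec.contig}:{rec.pos} lacks depth fields; skipped",
                        stacklevel=2,
                    )
                    continue
                out.append(cr)
    return out


def merge_callers(
    per_caller: dict[str, list[CallRecord]],
    panel_id: str = "",
    replicate_id: str = "",
    assay: Assay = Assay.RNA,
    priority: list[str] | None = None,
) -> CallSet:
    """Merge per-caller record lists into one multi-caller :class:`CallSet`.

    Caller membership is the union over callers reporting each key; the
    evidence triple comes from the highest-priority caller (``priority``
    defaults to the dict's insertion order).  Flags are unioned.
    """
    priority = list(priority if priority is not None else per_caller)
    rank = {c: i for i, c in enumerate(priority)}

    merged: dict[VariantKey, CallRecord] = {}
    chosen_rank: dict[VariantKey, int] = {}
    ref_seen: dict[tuple[str, int, str], str] = {}
    for caller, records in per_caller.items():
        for rec in records:
            key = rec.key
            locus_alt = (key.chrom, key.pos, key.alt)
            prior_ref = ref_seen.setdefault(locus_alt, key.ref)
            if prior_ref != key.ref:
                raise ValueError(
                    f"conflicting REF alleles at {key.chrom}:{key.pos} (alt {key.alt}): "
                    f"{prior_ref} vs {key.ref} — inputs not consistently normalised"
                )
            prev = merged.get(key)
            if prev is None:
                merged[key] = replace(rec, callers=frozenset({caller}))
                chosen_rank[key] = rank.get(caller, len(rank))
            else:
                callers = prev.callers | {caller}
                flags = prev.flags | rec.flags
                r = rank.get(caller, len(rank))
                if r < chosen_rank[key]:
                    merged[key] = replace(rec, callers=callers, flags=flags)
                    chosen_rank[key] = r
                else:
                    merged[key] = replace(prev, callers=callers, flags=flags)
    return CallSet(panel_id, replicate_id, assay, merged)


def restrict_callset(c: CallSet, r: RegionSet) -> CallSet:
    """Keep only records whose anchor position lies inside ``r``."""
    kept = {k: v for k, v in c.records.items() if r.contains(k.chrom, k.pos)}
    return c.with_records(kept)


# ---------------------------------------------------------------------------
# Canonical TSV representation (chrom, pos, ref, alt, vaf, dp, adp, callers, flags)

_TSV_COLS = ["chrom", "pos", "ref", "alt", "vaf", "dp", "adp", "callers", "flags"]


def write_callset_tsv(c: CallSet, path: str | Path) -> None:
    rows = [
        {
            "chrom": r.key.chrom,
            "pos": r.key.pos,
            "ref": r.key.ref,
            "alt": r.key.alt,
            "vaf": round(r.vaf, 4),
            "dp": r.dp,
            "adp": r.adp,
            "callers": ",".join(sorted(r.callers)),
            "flags": ",".join(sorted(r.flags)),
        }
        for r in sorted(c.records.values(), key=lambda r: r.key)
    ]
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


def read_callset_tsv(
    path: str | Path, panel_id: str = "", replicate_id: str = "", assay: Assay = Assay.RNA
) -> CallSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    records: dict[VariantKey, CallRecord] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        records[key] = CallRecord(
            key=key,
            vaf=float(row.vaf),
            dp=int(row.dp),
            adp=int(row.adp),
            callers=frozenset(str(row.callers).split(",")) - {""},
            flags=frozenset(str(row.flags).split(",")) - {""},
        )
    return CallSet(panel_id, replicate_id, assay, records)
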