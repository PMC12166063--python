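"""Explanatory taxonomies for missed, panel-unique and RNA-unique variants.

Two ordered, short-circuit taxonomies partition their input sets (percentages
sum to 100%):

* Missed known positives under the non-stringent profile: not expressed →
  low VAF (< 2%) → low DP (< 20) → low ADP (< 2).
* Panel-unique variants, explained from the other panel's pre-filter
  evidence: detected by no caller → by exactly one caller → failed the other
  panel's (higher, calibrated) VAF cutoff → failed another filter (DP/ADP).

Also here: RNA-unique variant discovery against paired DNA replicates, and
evidence-level merging of replicate libraries (summed depths) emulating a
doubled-coverage merged library.
"""

from __future__ import annotations

import enum
from dataclasses import replace

from .callset import Assay, CallRecord, CallSet
from .filtering import FilterProfile

__all__ = [
    "MissedCategory",
    "UniqueAttribution",
    "categorize_missed_kp",
    "attribute_panel_unique",
    "find_rna_unique",
    "merge_replicate_evidence",
]


class MissedCategory(enum.Enum):
    NOT_EXPRESSED = "not_expressed"
    LOW_VAF = "low_vaf"
    LOW_DP = "low_dp"
    LOW_ADP = "low_adp"


class UniqueAttribution(enum.Enum):
    NO_CALLER = "no_caller"
    ONE_CALLER_ONLY = "one_caller_only"
    FAILED_VAF_CUTOFF = "failed_vaf_cutoff"
    OTHER_FILTER = "other_filter"


def categorize_missed_kp(
    evidence: CallRecord | None,
    expression: int,
    vaf_min: float = 0.02,
    dp_min: int = 20,
    adp_min: int = 2,
) -> MissedCategory:
    """Why a truth KP is absent from the non-stringent final call set.

    Ordered evaluation: no expression (or no evidence at all) → low VAF →
    low DP → low ADP.  Evidence passing all three thresholds contradicts the
    premise that the variant was missed and raises.
    """
    if expression == 0 or evidence is None:
        return MissedCategory.NOT_EXPRESSED
    if evidence.vaf < vaf_min:
        return MissedCategory.LOW_VAF
    if evidence.dp < dp_min:
        return MissedCategory.LOW_DP
    if evidence.adp < adp_min:
        return MissedCategory.LOW_ADP
    raise ValueError(
        f"evidence at {evidence.key.chrom}:{evidence.key.pos} passes all thresholds; "
        "the variant should not be missing"
    )


def attribute_panel_unique(
    key, other_panel_prefilter: CallSet, other_profile: FilterProfile
) -> UniqueAttribution:
    """Why the other panel's final calls miss a variant this panel reports.

    ``other_panel_prefilter`` is the other panel's merged multi-caller call
    set before any filtering; ``other_profile`` its final calibrated profile.
    """
    rec = other_panel_prefilter.records.get(key)
    if rec is None:
        return UniqueAttribution.NO_CALLER
    if len(rec.callers) == 1:
        return UniqueAttribution.ONE_CALLER_ONLY
    if rec.vaf < other_profile.vaf_min:
        return UniqueAttribution.FAILED_VAF_CUTOFF
    if rec.dp < other_profile.dp_min or rec.adp < other_profile.adp_min:
        return UniqueAttribution.OTHER_FILTER
    raise ValueError(
        f"{key.chrom}:{key.pos} passes the other panel's profile; it is not panel-unique"
    )


def find_rna_unique(
    rna_reps: list[CallSet], dna_reps: list[CallSet]
) -> dict:
    """Union over replicates of RNA-only variants, with per-replicate provenance.

    For each replicate i, the unique set is keys(rna_i) \\ keys(dna_i); the
    result maps each union key to the set of replicate ids in which it was
    RNA-only.  Inputs must be final (filtered) call sets restricted to the
    same region; clustered-flagged calls should be excluded upstream.
    """
    if len(rna_reps) != len(dna_reps):
        raise ValueError(
            f"replicate count mismatch: {len(rna_reps)} RNA vs {len(dna_reps)} DNA"
        )
    out: dict = {}
    for rna, dna in zip(rna_reps, dna_reps):
        for key in rna.keys() - dna.keys():
            out.setdefault(key, set()).add(rna.replicate_id)
    return out


def merge_replicate_evidence(a: CallSet, b: CallSet) -> CallSet:
    """Pool two replicates' evidence, emulating a merged (double-depth) library.

    Shared keys get summed DP/ADP with VAF recomputed as ADP'/DP'; caller sets
    and flags are unioned.  Keys present in only one replicate carry their
    evidence over unchanged.
    """
    if a.assay is not b.assay:
        raise ValueError(f"assay mismatch: {a.assay} vs {b.assay}")
    if a.panel_id != b.panel_id:
        raise ValueError(f"panel mismatch: {a.panel_id} vs {b.panel_id}")
    records = dict(a.records)
    for key, rb in b.records.items():
        ra = records.get(key)
        if ra is None:
            records[key] = rb
        else:
            dp = ra.dp + rb.dp
            adp = ra.adp + rb.adp
            records[key] = replace(
                ra,
                dp=dp,
                adp=adp,
                vaf=(adp / dp if dp else 0.0),
                callers=ra.callers | rb.callers,
                flags=ra.flags | rb.flags,
            )
    return CallSet(
        panel_id=a.panel_id,
        replicate_id=f"{a.replicate_id}+{b.replicate_id}",
        assay=a.assay,
        records=records,
    )
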