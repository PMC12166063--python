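"""End-to-end evaluation scenarios on a simulated (or assembled) cohort.

Scenario 1 — RNA-seq verifies and prioritises DNA variants: a non-stringent
pass (VAF >= 2%, DP >= 20, ADP >= 2, any caller) maximises recall, missed
known positives are categorised (not expressed / low VAF / low DP / low ADP),
then the consensus profile's VAF cutoff is calibrated to a relaxed FPR
set-point of 50 per million KN bases and recall is compared before/after.

Scenario 2 — standalone RNA-seq variant detection: starting from the
stringent consensus profile (2-of-3 callers, VAF >= 2%, DP >= 20, ADP >= 4),
clustered artifact calls are flagged and excluded, the VAF cutoff is
calibrated per replicate to a stringent set-point of 5 per million KN bases,
and the final call sets are scored for recall, PPV bounds, boundary-corrected
reproducibility, RNA-unique variants against paired DNA, and DNA/RNA VAF
concordance.

Panel comparison restricts two panels' final calls to their overlapping
target region and attributes each panel-unique variant to the reason the
other panel missed it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import asdict, dataclass, field

import numpy as np

from .callset import Assay, CallSet
from .expression import ExonIndex
from .filtering import DNA_COMPARISON, NON_STRINGENT, STRINGENT_BASE, FilterProfile, apply_filter
from .fpr import CalibrationResult, calibrate_vaf_cutoff, drop_flagged, estimate_fpr, flag_clustered
from .metrics import (
    ConcordanceStats,
    PpvBounds,
    ReproPair,
    ppv_bounds,
    recall,
    reproducibility_matrix,
    vaf_concordance,
)
from .simulate import SimulatedCohort
from .triage import (
    MissedCategory,
    UniqueAttribution,
    attribute_panel_unique,
    categorize_missed_kp,
    find_rna_unique,
)

__all__ = [
    "EvaluationReport",
    "PanelCompareReport",
    "run_scenario1",
    "run_scenario2",
    "run_panel_compare",
    "FPR_TARGET_VERIFICATION",
    "FPR_TARGET_STANDALONE",
]

#: relaxed FPR set-point (FP per million KN bases) when RNA verifies DNA variants
FPR_TARGET_VERIFICATION = 50.0
#: stringent FPR set-point for standalone RNA-seq detection
FPR_TARGET_STANDALONE = 5.0


@dataclass
class EvaluationReport:
    """Per-panel scenario outcome; all rates derive from the counts it carries."""

    panel_id: str
    scenario: str
    profile_name: str
    target_fpr: float
    calibrations: list[CalibrationResult] = field(default_factory=list)
    mean_vaf_cutoff: float = float("nan")
    mean_fpr: float = float("nan")
    recall_non_stringent: float = float("nan")
    recall_calibrated: float = float("nan")
    missed_categories: dict[str, int] = field(default_factory=dict)
    ppv: PpvBounds | None = None
    reproducibility: list[ReproPair] = field(default_factory=list)
    mean_reproducibility: float = float("nan")
    concordance: ConcordanceStats | None = None
    n_rna_unique: int = 0
    recall_wts: float = float("nan")

    def to_dict(self) -> dict:
        d = {
            "panel_id": self.panel_id,
            "scenario": self.scenario,
            "profile_name": self.profile_name,
            "target_fpr": self.target_fpr,
            "mean_vaf_cutoff": self.mean_vaf_cutoff,
            "mean_fpr": self.mean_fpr,
            "recall_non_stringent": self.recall_non_stringent,
            "recall_calibrated": self.recall_calibrated,
            "missed_categories": dict(self.missed_categories),
            "mean_reproducibility": self.mean_reproducibility,
            "n_rna_unique": self.n_rna_unique,
            "recall_wts": self.recall_wts,
            "calibrations": [
                {
                    "calibrated_vaf_min": c.calibrated_vaf_min,
                    "achieved_fpr": c.achieved_fpr,
                    "target_fpr": c.target_fpr,
                    "attainable": c.attainable,
                }
                for c in self.calibrations
            ],
            "reproducibility": [asdict(p) for p in self.reproducibility],
        }
        if self.ppv is not None:
            d["ppv"] = asdict(self.ppv) | {"n_total": self.ppv.n_total}
        if self.concordance is not None:
            d["concordance"] = asdict(self.concordance)
        return d


def _calibrated_finals(
    cohort: SimulatedCohort,
    panel: str,
    target_fpr: float,
    base: FilterProfile = STRINGENT_BASE,
    exclude_clustered: bool = True,
    grid_step: float = 0.001,
    assay: Assay = Assay.RNA,
) -> tuple[list[CallSet], list[FilterProfile], list[CalibrationResult], list[CallSet]]:
    """Per-replicate (prefilter, calibrated profile, final) for one panel/assay."""
    truth = cohort.truth_for(panel)
    prefilters, profiles, calibrations, finals = [], [], [], []
    for rep_id in cohort.replicate_ids():
        pre = cohort.merged_callset(panel, assay, rep_id)
        if exclude_clustered:
            pre = drop_flagged(flag_clustered(pre))
        cal = calibrate_vaf_cutoff(pre, truth, base, target_fpr, grid_step)
        prof = base.with_vaf_min(cal.calibrated_vaf_min)
        prefilters.append(pre)
        profiles.append(prof)
        calibrations.append(cal)
        finals.append(apply_filter(pre, prof))
    return prefilters, profiles, calibrations, finals


def run_scenario1(cohort: SimulatedCohort, panel: str) -> EvaluationReport:
    """Non-stringent recall, missed-KP taxonomy, then FPR-50 consensus calibration."""
    truth = cohort.truth_for(panel)
    exon_index = ExonIndex(cohort.exons)
    reps = cohort.replicate_ids()

    recalls_ns: list[float] = []
    missed_counts: Counter = Counter()
    for rep_id in reps:
        pre = cohort.merged_callset(panel, Assay.RNA, rep_id)
        final_ns = apply_filter(pre, NON_STRINGENT)
        recalls_ns.append(recall(final_ns, truth))
        for key in set(truth.kp) - final_ns.keys():
            cat = categorize_missed_kp(
                pre.records.get(key), exon_index.expression(key)
            )
            missed_counts[cat.value] += 1

    _, _, calibrations, finals = _calibrated_finals(
        cohort, panel, FPR_TARGET_VERIFICATION, exclude_clustered=False
    )
    recalls_cal = [recall(f, truth) for f in finals]
    fprs = [estimate_fpr(f, truth) for f in finals]

    return EvaluationReport(
        panel_id=panel,
        scenario="scenario1",
        profile_name=STRINGENT_BASE.name,
        target_fpr=FPR_TARGET_VERIFICATION,
        calibrations=calibrations,
        mean_vaf_cutoff=float(np.mean([c.calibrated_vaf_min for c in calibrations])),
        mean_fpr=float(np.mean(fprs)),
        recall_non_stringent=float(np.mean(recalls_ns)),
        recall_calibrated=float(np.mean(recalls_cal)),
        missed_categories={c.value: missed_counts.get(c.value, 0) for c in MissedCategory},
    )


def run_scenario2(cohort: SimulatedCohort, panel: str) -> EvaluationReport:
    """Standalone RNA detection under the stringent FPR set-point of 5/Mb."""
    truth = cohort.truth_for(panel)
    prefilters, profiles, calibrations, finals = _calibrated_finals(
        cohort, panel, FPR_TARGET_STANDALONE, exclude_clustered=True
    )
    recalls = [recall(f, truth) for f in finals]
    fprs = [estimate_fpr(f, truth) for f in finals]
    ppv = ppv_bounds(finals[0], truth) if len(finals[0]) else None
    pairs, mean_repro = reproducibility_matrix(prefilters, profiles)

    # paired DNA-seq finals: fixed stringent DNA comparison profile
    dna_finals = [
        apply_filter(cohort.merged_callset(panel, Assay.DNA, rep_id), DNA_COMPARISON)
        for rep_id in cohort.replicate_ids()
    ]
    rna_unique = find_rna_unique(finals, dna_finals)

    concordance = None
    shared = finals[0].keys() & dna_finals[0].keys()
    if len(shared) >= 2:
        concordance = vaf_concordance(dna_finals[0], finals[0])

    recall_wts = float("nan")
    if cohort.cfg.include_wts:
        _, _, _, wts_finals = _calibrated_finals(
            cohort, panel, FPR_TARGET_STANDALONE, exclude_clustered=True, assay=Assay.WTS
        )
        recall_wts = float(np.mean([recall(f, truth) for f in wts_finals]))

    return EvaluationReport(
        panel_id=panel,
        scenario="scenario2",
        profile_name=STRINGENT_BASE.name,
        target_fpr=FPR_TARGET_STANDALONE,
        calibrations=calibrations,
        mean_vaf_cutoff=float(np.mean([c.calibrated_vaf_min for c in calibrations])),
        mean_fpr=float(np.mean(fprs)),
        recall_calibrated=float(np.mean(recalls)),
        ppv=ppv,
        reproducibility=pairs,
        mean_reproducibility=mean_repro,
        concordance=concordance,
        n_rna_unique=len(rna_unique),
        recall_wts=recall_wts,
    )


@dataclass
class PanelCompareReport:
    """Two panels' final calls compared inside their overlapping target region."""

    panel_a: str
    panel_b: str
    overlap_size: int
    n_a: int
    n_b: int
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    concordance_a_to_b: float  # share of A's overlap calls also made by B
    concordance_b_to_a: float
    attribution_a: dict[str, int] = field(default_factory=dict)
    attribution_b: dict[str, int] = field(default_factory=dict)
    attribution_a_pct: dict[str, float] = field(default_factory=dict)
    attribution_b_pct: dict[str, float] = field(default_factory=dict)
    vaf_concordance: ConcordanceStats | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _attribution(
    unique_keys: set, other_prefilter: CallSet, other_profile: FilterProfile
) -> tuple[dict[str, int], dict[str, float]]:
    counts: Counter = Counter(
        attribute_panel_unique(k, other_prefilter, other_profile).value
        for k in unique_keys
    )
    total = sum(counts.values())
    full = {c.value: counts.get(c.value, 0) for c in UniqueAttribution}
    pct = {k: (100.0 * v / total if total else 0.0) for k, v in full.items()}
    return full, pct


def run_panel_compare(
    cohort: SimulatedCohort, panel_a: str, panel_b: str, rep_id: str | None = None
) -> PanelCompareReport:
    """Compare two panels' FPR-5 final calls in their overlap (one replicate)."""
    from .regions import intersect

    region_a = cohort.analysis_region(panel_a)
    region_b = cohort.analysis_region(panel_b)
    overlap = intersect(region_a, region_b, label="overlap")
    if overlap.total_size == 0:
        raise ValueError(f"panels {panel_a} and {panel_b} do not overlap")
    rep_id = rep_id or cohort.replicate_ids()[0]
    rep_index = cohort.replicate_ids().index(rep_id)

    finals, prefilters, profiles = {}, {}, {}
    for panel in (panel_a, panel_b):
        pres, profs, _, fins = _calibrated_finals(
            cohort, panel, FPR_TARGET_STANDALONE, exclude_clustered=True
        )
        from .callset import restrict_callset

        prefilters[panel] = pres[rep_index]
        profiles[panel] = profs[rep_index]
        finals[panel] = restrict_callset(fins[rep_index], overlap)

    keys_a, keys_b = finals[panel_a].keys(), finals[panel_b].keys()
    shared = keys_a & keys_b
    unique_a = keys_a - keys_b
    unique_b = keys_b - keys_a

    attr_a, attr_a_pct = _attribution(unique_a, prefilters[panel_b], profiles[panel_b])
    attr_b, attr_b_pct = _attribution(unique_b, prefilters[panel_a], profiles[panel_a])

    conc = None
    if len(shared) >= 2:
        conc = vaf_concordance(finals[panel_a], finals[panel_b])

    return PanelCompareReport(
        panel_a=panel_a,
        panel_b=panel_b,
        overlap_size=overlap.total_size,
        n_a=len(keys_a),
        n_b=len(keys_b),
        n_shared=len(shared),
        n_unique_a=len(unique_a),
        n_unique_b=len(unique_b),
        concordance_a_to_b=(len(shared) / len(keys_a) if keys_a else float("nan")),
        concordance_b_to_a=(len(shared) / len(keys_b) if keys_b else float("nan")),
        attribution_a=attr_a,
        attribution_b=attr_b,
        attribution_a_pct=attr_a_pct,
        attribution_b_pct=attr_b_pct,
        vaf_concordance=conc,
    )
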