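"""Missed-KP and panel-unique taxonomies, RNA-unique discovery, evidence merging."""

import numpy as np
import pytest

from rnavarbench.callset import Assay
from rnavarbench.filtering import FilterProfile
from rnavarbench.triage import (
    MissedCategory,
    UniqueAttribution,
    attribute_panel_unique,
    categorize_missed_kp,
    find_rna_unique,
    merge_replicate_evidence,
)

from conftest import make_callset, make_key, make_record


class TestCategorizeMissedKp:
    def test_not_expressed(self):
        assert categorize_missed_kp(None, 0) is MissedCategory.NOT_EXPRESSED
        ev = make_record(1, vaf=0.5, dp=100, adp=50)
        assert categorize_missed_kp(ev, 0) is MissedCategory.NOT_EXPRESSED
        assert categorize_missed_kp(None, 900) is MissedCategory.NOT_EXPRESSED

    def test_low_vaf_low_dp_low_adp_ordered(self):
        low_vaf = make_record(1, vaf=0.012, dp=400, adp=5)
        assert categorize_missed_kp(low_vaf, 812) is MissedCategory.LOW_VAF
        low_dp = make_record(1, vaf=0.3, dp=10, adp=3)
        assert categorize_missed_kp(low_dp, 10) is MissedCategory.LOW_DP
        low_adp = make_record(1, vaf=0.05, dp=20, adp=1)
        assert categorize_missed_kp(low_adp, 10) is MissedCategory.LOW_ADP

    def test_contradiction_when_evidence_passes(self):
        good = make_record(1, vaf=0.05, dp=100, adp=5)
        with pytest.raises(ValueError, match="should not be missing"):
            categorize_missed_kp(good, 100)

    def test_partitions_a_missed_set(self):
        rng = np.random.default_rng(40)
        counts = {c: 0 for c in MissedCategory}
        for i in range(200):
            expr = int(rng.integers(0, 3) == 0) * int(rng.integers(1, 1000))
            if rng.random() < 0.3:
                ev = None
            else:
                dp = int(rng.integers(1, 100))
                adp = int(rng.integers(0, min(dp, 3) + 1))
                ev = make_record(i + 1, vaf=adp / dp, dp=dp, adp=adp)
                if ev.vaf >= 0.02 and ev.dp >= 20 and ev.adp >= 2 and expr > 0:
                    continue  # would contradict "missed"
            counts[categorize_missed_kp(ev, expr)] += 1
        assert sum(counts.values()) > 0  # every processed item got exactly one category


OTHER = FilterProfile("other_final", vaf_min=0.057, dp_min=20, adp_min=4, min_callers=2)


class TestAttributePanelUnique:
    def test_four_way_taxonomy(self):
        key = make_key(500)
        empty_other = make_callset([])
        assert attribute_panel_unique(key, empty_other, OTHER) is UniqueAttribution.NO_CALLER

        one = make_callset([make_record(500, vaf=0.1, dp=100, adp=10, callers=("vardict",))])
        assert attribute_panel_unique(key, one, OTHER) is UniqueAttribution.ONE_CALLER_ONLY

        low_vaf = make_callset(
            [make_record(500, vaf=0.045, dp=200, adp=9, callers=("c1", "c2"))]
        )
        assert attribute_panel_unique(key, low_vaf, OTHER) is UniqueAttribution.FAILED_VAF_CUTOFF

        low_adp = make_callset(
            [make_record(500, vaf=0.1, dp=30, adp=3, callers=("c1", "c2"))]
        )
        assert attribute_panel_unique(key, low_adp, OTHER) is UniqueAttribution.OTHER_FILTER

    def test_not_unique_raises(self):
        key = make_key(500)
        passing = make_callset([make_record(500, vaf=0.1, dp=100, adp=10, callers=("c1", "c2"))])
        with pytest.raises(ValueError, match="not panel-unique"):
            attribute_panel_unique(key, passing, OTHER)

    def test_partitions_random_unique_set(self):
        rng = np.random.default_rng(41)
        other_records = []
        for p in range(1, 300):
            if rng.random() < 0.3:
                continue  # no caller saw it
            dp = int(rng.integers(20, 400))
            adp = int(rng.integers(1, max(2, dp // 10)))
            n_callers = int(rng.integers(1, 4))
            r = make_record(p, vaf=adp / dp, dp=dp, adp=adp,
                            callers=tuple(f"c{j}" for j in range(1, n_callers + 1)))
            other_records.append(r)
        other = make_callset(other_records)
        labels = {}
        for p in range(1, 300):
            try:
                labels[p] = attribute_panel_unique(make_key(p), other, OTHER)
            except ValueError:
                continue  # genuinely not unique
        assert len(labels) > 100
        assert set(labels.values()) <= set(UniqueAttribution)


class TestFindRnaUnique:
    def _sets(self, rna_keys_per_rep, dna_keys_per_rep):
        rna = [make_callset([make_record(p) for p in keys], rep=f"rep{i+1}", assay=Assay.RNA)
               for i, keys in enumerate(rna_keys_per_rep)]
        dna = [make_callset([make_record(p) for p in keys], rep=f"rep{i+1}", assay=Assay.DNA)
               for i, keys in enumerate(dna_keys_per_rep)]
        return rna, dna

    def test_identical_sets_give_empty_union(self):
        rna, dna = self._sets([[1, 2], [3, 4]], [[1, 2], [3, 4]])
        assert find_rna_unique(rna, dna) == {}

    def test_provenance_tracks_contributing_replicate(self):
        rna, dna = self._sets([[1], [1, 99], [1]], [[1], [1], [1]])
        out = find_rna_unique(rna, dna)
        assert {k.pos: v for k, v in out.items()} == {99: {"rep2"}}

    def test_matches_per_replicate_set_difference_oracle(self):
        rng = np.random.default_rng(42)
        rna_keys = [set(rng.integers(1, 60, 30).tolist()) for _ in range(4)]
        dna_keys = [set(rng.integers(1, 60, 30).tolist()) for _ in range(4)]
        rna, dna = self._sets([sorted(s) for s in rna_keys], [sorted(s) for s in dna_keys])
        out = {k.pos: v for k, v in find_rna_unique(rna, dna).items()}
        oracle: dict = {}
        for i, (r, d) in enumerate(zip(rna_keys, dna_keys)):
            for p in r - d:
                oracle.setdefault(p, set()).add(f"rep{i+1}")
        assert out == oracle

    def test_replicate_count_mismatch(self):
        rna, dna = self._sets([[1]], [[1], [2]])
        with pytest.raises(ValueError, match="mismatch"):
            find_rna_unique(rna, dna)


class TestMergeReplicateEvidence:
    def test_shared_key_sums_depths_and_recomputes_vaf(self):
        a = make_callset([make_record(5, vaf=0.1, dp=300, adp=30, callers=("c1",))], rep="r1")
        b = make_callset([make_record(5, vaf=34 / 320, dp=320, adp=34, callers=("c2",))], rep="r2")
        merged = merge_replicate_evidence(a, b)
        (rec,) = merged.records.values()
        assert (rec.dp, rec.adp) == (620, 64)
        assert rec.vaf == pytest.approx(64 / 620)
        assert rec.callers == {"c1", "c2"}
        assert merged.replicate_id == "r1+r2"

    def test_merge_with_empty_is_identity(self):
        a = make_callset([make_record(5), make_record(7)], rep="r1")
        empty = make_callset([], rep="r2")
        merged = merge_replicate_evidence(a, empty)
        assert merged.records == a.records

    def test_assay_mismatch_raises(self):
        a = make_callset([make_record(5)], assay=Assay.RNA)
        b = make_callset([make_record(5)], assay=Assay.DNA)
        with pytest.raises(ValueError, match="assay"):
            merge_replicate_evidence(a, b)

    def test_merged_median_depth_doubles_on_cohort(self, small_cohort):
        """Pooling two replicate libraries roughly doubles the median variant depth."""
        panel = small_cohort.panel_labels[0]
        a = small_cohort.merged_callset(panel, Assay.RNA, "rep1")
        b = small_cohort.merged_callset(panel, Assay.RNA, "rep2")
        merged = merge_replicate_evidence(a, b)
        shared = a.keys() & b.keys()
        assert len(shared) > 20
        med_single = np.median([a.records[k].dp for k in shared])
        med_merged = np.median([merged.records[k].dp for k in shared])
        assert med_merged == pytest.approx(2 * med_single, rel=0.25)
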