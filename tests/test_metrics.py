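"""Recall/PPV arithmetic, boundary-corrected reproducibility, VAF concordance."""

import numpy as np
import pytest

from rnavarbench.filtering import FilterProfile
from rnavarbench.metrics import (
    ppv_bounds,
    recall,
    reproducibility,
    reproducibility_matrix,
    vaf_concordance,
)
from rnavarbench.regions import Interval, RegionSet
from rnavarbench.truth import TruthSet

from conftest import make_callset, make_key, make_record


class TestRecall:
    def test_half_and_full(self, toy_truth):
        kp_keys = sorted(toy_truth.kp)
        half = make_callset([make_record(k.pos, alt=k.alt) for k in kp_keys[:10]])
        assert recall(half, toy_truth) == pytest.approx(0.5)
        full = make_callset([make_record(k.pos, alt=k.alt) for k in kp_keys])
        assert recall(full, toy_truth) == pytest.approx(1.0)

    def test_matches_set_intersection_oracle(self, toy_truth):
        rng = np.random.default_rng(20)
        keys = [make_key(int(p), alt="T") for p in rng.integers(1, 10_000, 80)]
        cs = make_callset([make_record(k.pos, alt=k.alt) for k in set(keys)])
        want = len(set(toy_truth.kp) & cs.keys()) / len(toy_truth.kp)
        assert recall(cs, toy_truth) == pytest.approx(want)

    def test_empty_truth_raises(self):
        t = TruthSet(kp={}, kn={}, region=RegionSet([Interval("chr1", 0, 10)]))
        with pytest.raises(ValueError):
            recall(make_callset([]), t)


class TestPpvBounds:
    def test_printed_regime_example(self):
        """960 KP + 35 unknown + 5 FP of 1000 calls -> bounds 0.960 / 0.995."""
        region = RegionSet([Interval("chr1", 0, 100_000)])
        kp = {make_key(i, alt="T"): 0.1 for i in range(1, 961)}
        kn = np.arange(50_000, 50_005, dtype=np.int64)
        t = TruthSet(kp=kp, kn={"chr1": kn}, region=region)
        calls = [make_record(k.pos, alt=k.alt) for k in kp]
        calls += [make_record(int(p)) for p in kn]  # 5 FPs
        calls += [make_record(60_000 + i) for i in range(35)]  # uncharacterized
        b = ppv_bounds(make_callset(calls), t)
        assert (b.n_kp, b.n_unknown, b.n_fp, b.n_total) == (960, 35, 5, 1000)
        assert b.lower == pytest.approx(0.960)
        assert b.upper == pytest.approx(0.995)

    def test_degenerate_cases(self, toy_truth):
        kp_keys = sorted(toy_truth.kp)
        all_kp = make_callset([make_record(k.pos, alt=k.alt) for k in kp_keys])
        b = ppv_bounds(all_kp, toy_truth)
        assert b.lower == b.upper == 1.0
        only_fp = make_callset([make_record(10), make_record(30)])
        b2 = ppv_bounds(only_fp, toy_truth)
        assert b2.lower == b2.upper == 0.0
        with pytest.raises(ValueError):
            ppv_bounds(make_callset([]), toy_truth)

    def test_lower_never_exceeds_upper(self, toy_truth):
        rng = np.random.default_rng(21)
        cs = make_callset([make_record(int(p), alt="T") for p in rng.integers(1, 10_000, 200)])
        b = ppv_bounds(cs, toy_truth)
        assert 0.0 <= b.lower <= b.upper <= 1.0


PROFILE = FilterProfile("final", vaf_min=0.037, dp_min=20, adp_min=4, min_callers=1)


class TestReproducibility:
    def test_identical_call_sets(self):
        recs = [make_record(i * 50, vaf=0.1, dp=100, adp=10) for i in range(1, 30)]
        a = make_callset(recs, rep="rep1")
        b = make_callset(recs, rep="rep2")
        pair = reproducibility(a, b, PROFILE, PROFILE)
        assert pair.a_to_b == pair.b_to_a == 1.0

    def test_boundary_pair_rescued_by_relaxed_cutoff(self):
        """A 3.8% vs 3.6% VAF pair straddling a 3.7% cutoff counts as reproducible."""
        a = make_callset([make_record(100, vaf=0.038, dp=500, adp=19)], rep="A")
        b = make_callset([make_record(100, vaf=0.036, dp=500, adp=18)], rep="B")
        pair = reproducibility(a, b, PROFILE, PROFILE, relaxed_vaf_min=0.02)
        assert pair.a_to_b == 1.0  # found in B once B is relaxed to 2%
        # B's own final set is empty under its 3.7% cutoff: direction undefined
        assert np.isnan(pair.b_to_a)
        # without the relaxation the variant is (wrongly) lost
        strict = reproducibility(a, b, PROFILE, PROFILE, relaxed_vaf_min=PROFILE.vaf_min)
        assert strict.a_to_b == 0.0

    def test_disjoint_sets_zero_both_ways(self):
        a = make_callset([make_record(i, vaf=0.1, dp=100) for i in range(100, 110)], rep="A")
        b = make_callset([make_record(i, vaf=0.1, dp=100) for i in range(500, 510)], rep="B")
        pair = reproducibility(a, b, PROFILE, PROFILE)
        assert pair.a_to_b == 0.0 and pair.b_to_a == 0.0

    def test_relaxing_never_decreases(self):
        rng = np.random.default_rng(22)
        def rand_set(rep):
            return make_callset(
                [make_record(int(p), vaf=float(round(v, 3)), dp=1000, adp=int(round(round(v, 3) * 1000)))
                 for p, v in zip(rng.choice(np.arange(1, 5000), 100, replace=False),
                                 rng.uniform(0.02, 0.08, 100))],
                rep=rep,
            )
        a, b = rand_set("A"), rand_set("B")
        loose = reproducibility(a, b, PROFILE, PROFILE, relaxed_vaf_min=0.02)
        tight = reproducibility(a, b, PROFILE, PROFILE, relaxed_vaf_min=0.03)
        assert loose.a_to_b >= tight.a_to_b

    def test_four_replicates_give_twelve_directed_values_matching_oracle(self):
        rng = np.random.default_rng(23)
        sets = []
        for rep in range(4):
            recs = [
                make_record(int(p), vaf=float(round(v, 3)), dp=1000,
                            adp=int(round(round(v, 3) * 1000)))
                for p, v in zip(rng.choice(np.arange(1, 3000), 80, replace=False),
                                rng.uniform(0.02, 0.10, 80))
            ]
            sets.append(make_callset(recs, rep=f"rep{rep + 1}"))
        profiles = [PROFILE] * 4
        pairs, mean = reproducibility_matrix(sets, profiles)
        directed = [v for p in pairs for v in (p.a_to_b, p.b_to_a)]
        assert len(directed) == 12
        # set-arithmetic oracle per direction
        from rnavarbench.filtering import apply_filter

        for p in pairs:
            i = int(p.a_id[-1]) - 1
            j = int(p.b_id[-1]) - 1
            fa = apply_filter(sets[i], PROFILE).keys()
            rb = apply_filter(sets[j], PROFILE.with_vaf_min(0.02)).keys()
            assert p.a_to_b == pytest.approx(len(fa & rb) / len(fa))
        vals = [v for v in directed if not np.isnan(v)]
        assert mean == pytest.approx(np.mean(vals))


class TestVafConcordance:
    def test_perfect_agreement(self):
        recs = [
            make_record(i * 10, vaf=0.01 * i, dp=100 + 10 * i,
                        adp=round(0.01 * i * (100 + 10 * i)))
            for i in range(1, 20)
        ]
        a = make_callset(recs, rep="A")
        b = make_callset(recs, rep="B")
        c = vaf_concordance(a, b)
        assert c.r_squared_vaf == pytest.approx(1.0)
        assert c.slope == pytest.approx(1.0)
        assert c.intercept == pytest.approx(0.0, abs=1e-12)
        assert c.r_squared_log2dp == pytest.approx(1.0)

    def test_noise_matches_analytic_variance_ratio(self):
        rng = np.random.default_rng(24)
        n = 2000
        x = rng.uniform(0.05, 0.45, n)
        sigma = 0.05
        y = np.clip(x + rng.normal(0, sigma, n), 0, 1)
        a = make_callset(
            [make_record(i + 1, vaf=float(x[i]), dp=1000, adp=int(round(x[i] * 1000)))
             for i in range(n)], rep="A")
        b = make_callset(
            [make_record(i + 1, vaf=float(y[i]), dp=1000, adp=int(round(y[i] * 1000)))
             for i in range(n)], rep="B")
        c = vaf_concordance(a, b)
        var_x = np.var(x)
        expected_r2 = var_x / (var_x + sigma**2)
        assert c.r_squared_vaf == pytest.approx(expected_r2, rel=0.05)
        assert c.slope == pytest.approx(1.0, abs=0.05)

    def test_shared_key_extraction_matches_join_oracle(self):
        rng = np.random.default_rng(25)
        pa = rng.choice(np.arange(1, 500), 100, replace=False)
        pb = rng.choice(np.arange(1, 500), 100, replace=False)
        a = make_callset(
            [make_record(int(p), vaf=(p % 50 + 1) / 500, dp=500, adp=int(p % 50 + 1))
             for p in pa], rep="A")
        b = make_callset(
            [make_record(int(p), vaf=(p % 40 + 1) / 500, dp=500, adp=int(p % 40 + 1))
             for p in pb], rep="B")
        shared = set(map(int, pa)) & set(map(int, pb))
        if len(shared) >= 2:
            c = vaf_concordance(a, b)
            assert c.n_shared == len(shared)

    def test_truth_set_as_reference(self, toy_truth):
        calls = [make_record(k.pos, vaf=v, dp=1000, adp=int(round(v * 1000)), alt=k.alt)
                 for k, v in toy_truth.kp.items()]
        c = vaf_concordance(make_callset(calls), toy_truth)
        assert c.n_shared == len(toy_truth.kp)
        assert c.r_squared_vaf == pytest.approx(1.0)
        assert np.isnan(c.r_squared_log2dp)

    def test_degenerate_variance_raises(self):
        a = make_callset([make_record(1, vaf=0.1, dp=100, adp=10),
                          make_record(2, vaf=0.1, dp=100, adp=10)], rep="A")
        with pytest.raises(ValueError):
            vaf_concordance(a, a)
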