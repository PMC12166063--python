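"""Recall, PPV bounds, boundary-corrected reproducibility and concordance.

With an incomplete truth set, precision cannot be computed exactly: calls that
are neither known-positive nor known-negative are *uncharacterized*.  The PPV
is therefore bracketed,

    upper PPV = (KP + uncharacterized) / total        (unknowns all positive)
    lower PPV =  KP / total                           (unknowns all negative)

and the true PPV lies within ``[lower, upper]``.

Reproducibility between two replicate libraries is the portion of one
library's final calls also found in the other; it is directional (the two
libraries need not call the same number of variants).  A hard VAF cutoff
introduces a boundary effect — a variant at 3.8% in LibA and 3.6% in LibB
under a 3.7% cutoff is really reproducible — so the comparison library is
re-filtered at a relaxed 2% VAF floor before membership is tested.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .callset import CallSet
from .filtering import FilterProfile, apply_filter
from .truth import ClassLabel, TruthSet, VariantKey

__all__ = [
    "PpvBounds",
    "ReproPair",
    "ConcordanceStats",
    "recall",
    "ppv_bounds",
    "reproducibility",
    "reproducibility_matrix",
    "vaf_concordance",
]


@dataclass(frozen=True)
class PpvBounds:
    lower: float
    upper: float
    n_kp: int
    n_unknown: int
    n_fp: int

    @property
    def n_total(self) -> int:
        return self.n_kp + self.n_unknown + self.n_fp


@dataclass(frozen=True)
class ReproPair:
    """Directed reproducibility between two replicates (not symmetric)."""

    a_id: str
    b_id: str
    a_to_b: float
    b_to_a: float


@dataclass(frozen=True)
class ConcordanceStats:
    n_shared: int
    r_squared_vaf: float
    r_squared_log2dp: float
    slope: float
    intercept: float


def recall(c: CallSet, t: TruthSet) -> float:
    """Fraction of truth KP variants (within the truth region) present in ``c``."""
    n_truth = len(t.kp)
    if n_truth == 0:
        raise ValueError("recall undefined: truth set has no KP variants")
    n_found = sum(1 for k in t.kp if k in c.records)
    return n_found / n_truth


def ppv_bounds(c: CallSet, t: TruthSet) -> PpvBounds:
    """Bracket the positive predictive value under the incomplete truth set."""
    if not c.records:
        raise ValueError("PPV undefined for an empty call set")
    counts = {label: 0 for label in ClassLabel}
    for k in c.records:
        counts[t.classify(k)] += 1
    n_kp = counts[ClassLabel.KP]
    n_unknown = counts[ClassLabel.UNCHARACTERIZED]
    n_fp = counts[ClassLabel.FP]
    n_total = n_kp + n_unknown + n_fp
    return PpvBounds(
        lower=n_kp / n_total,
        upper=(n_kp + n_unknown) / n_total,
        n_kp=n_kp,
        n_unknown=n_unknown,
        n_fp=n_fp,
    )


def _directed(
    a_final: CallSet, b_prefilter: CallSet, b_profile: FilterProfile, relaxed_vaf_min: float
) -> float:
    """|keys(a_final) ∩ keys(b at relaxed VAF)| / |keys(a_final)|."""
    if not a_final.records:
        return float("nan")
    b_relaxed = apply_filter(b_prefilter, b_profile.with_vaf_min(relaxed_vaf_min))
    a_keys = a_final.keys()
    return len(a_keys & b_relaxed.keys()) / len(a_keys)


def reproducibility(
    a: CallSet,
    b: CallSet,
    profile_a: FilterProfile,
    profile_b: FilterProfile,
    relaxed_vaf_min: float = 0.02,
) -> ReproPair:
    """Boundary-corrected directed reproducibility between two replicates.

    ``a`` and ``b`` are *pre-filter* call sets; each replicate's own final
    calls use its full (calibrated) profile, while membership in the partner is
    tested with the partner's profile relaxed to ``relaxed_vaf_min``.
    Directions with an empty final call set are reported as NaN.
    """
    a_final = apply_filter(a, profile_a)
    b_final = apply_filter(b, profile_b)
    return ReproPair(
        a_id=a.replicate_id,
        b_id=b.replicate_id,
        a_to_b=_directed(a_final, b, profile_b, relaxed_vaf_min),
        b_to_a=_directed(b_final, a, profile_a, relaxed_vaf_min),
    )


def reproducibility_matrix(
    callsets: list[CallSet],
    profiles: list[FilterProfile],
    relaxed_vaf_min: float = 0.02,
) -> tuple[list[ReproPair], float]:
    """All ordered replicate pairs (n·(n−1) directed values) and their mean."""
    if len(callsets) != len(profiles):
        raise ValueError("one profile per call set required")
    pairs = [
        reproducibility(callsets[i], callsets[j], profiles[i], profiles[j], relaxed_vaf_min)
        for i, j in itertools.combinations(range(len(callsets)), 2)
    ]
    values = [v for p in pairs for v in (p.a_to_b, p.b_to_a) if not np.isnan(v)]
    return pairs, (float(np.mean(values)) if values else float("nan"))


def _shared_pairs(a: CallSet, b: CallSet | TruthSet) -> list[tuple[VariantKey, float, float]]:
    if isinstance(b, TruthSet):
        return [(k, a.records[k].vaf, b.kp[k]) for k in a.records if k in b.kp]
    return [(k, a.records[k].vaf, b.records[k].vaf) for k in a.records if k in b.records]


def vaf_concordance(a: CallSet, b: CallSet | TruthSet) -> ConcordanceStats:
    """Least-squares concordance of VAF (and log2 depth) over shared variants.

    ``a`` supplies the predictor.  When ``b`` is a truth set the response is
    the truth VAF and the depth R² is undefined.  Complete-case: only shared
    keys enter; depth pairs additionally require both depths positive.
    """
    pairs = _shared_pairs(a, b)
    n_shared = len(pairs)
    if n_shared < 2:
        raise ValueError("concordance requires >= 2 shared variants")
    x = np.array([p[1] for p in pairs])
    y = np.array([p[2] for p in pairs])
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("concordance undefined: degenerate VAF variance")
    fit = stats.linregress(x, y)

    r2_dp = float("nan")
    if isinstance(b, CallSet):
        dpa = np.array([a.records[p[0]].dp for p in pairs], dtype=float)
        dpb = np.array([b.records[p[0]].dp for p in pairs], dtype=float)
        ok = (dpa > 0) & (dpb > 0)
        if ok.sum() >= 2 and np.ptp(dpa[ok]) > 0 and np.ptp(dpb[ok]) > 0:
            r2_dp = float(stats.linregress(np.log2(dpa[ok]), np.log2(dpb[ok])).rvalue ** 2)

    return ConcordanceStats(
        n_shared=n_shared,
        r_squared_vaf=float(fit.rvalue**2),
        r_squared_log2dp=r2_dp,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
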