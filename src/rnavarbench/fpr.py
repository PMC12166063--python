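"""False-positive-rate estimation and VAF-cutoff calibration.

The FPR is the number of calls landing on known-negative positions per million
KN bases:

    FPR = (# calls classified FP) / (# KN positions in panel & CTR) * 1e6

Because the truth set is positional and incomplete, uncharacterized calls never
enter the numerator, so the estimate is conservative.

Calibration raises the VAF cutoff of a base profile over a regular grid until
the estimated FPR drops to a target (e.g. 50/Mb when RNA-seq verifies DNA
variants, 5/Mb for standalone detection), returning the smallest grid cutoff
that achieves the target together with the full (cutoff, FPR) trace.  FPR is a
step function of the cutoff, so the grid makes minimality directly checkable.

Clustered artifact calls (runs of co-located calls, a known caller failure
mode) can be flagged and excluded before calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .callset import CallSet
from .filtering import FilterProfile, apply_filter, passes
from .truth import ClassLabel, TruthSet

__all__ = ["CalibrationResult", "estimate_fpr", "flag_clustered", "drop_flagged", "calibrate_vaf_cutoff"]

CLUSTERED_FLAG = "clustered"


def estimate_fpr(c: CallSet, t: TruthSet) -> float:
    """FP calls per million KN bases for the call set as given (no filtering)."""
    denom = t.kn_size
    if denom == 0:
        raise ValueError("FPR undefined: truth set has no KN positions")
    n_fp = sum(t.classify(k) is ClassLabel.FP for k in c.records)
    return n_fp / denom * 1_000_000


def flag_clustered(c: CallSet, window_bp: int = 200, min_calls: int = 5) -> CallSet:
    """Flag single-linkage runs of >= ``min_calls`` calls within ``window_bp``.

    Calls on the same chromosome are chained whenever consecutive positions are
    at most ``window_bp`` apart; every member of a chain of at least
    ``min_calls`` gains the ``"clustered"`` flag.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if min_calls < 2:
        raise ValueError("min_calls must be >= 2")
    by_chrom: dict[str, list] = {}
    for key in c.records:
        by_chrom.setdefault(key.chrom, []).append(key)
    flagged = set()
    for keys in by_chrom.values():
        keys.sort(key=lambda k: k.pos)
        run = [keys[0]]
        for k in keys[1:]:
            if k.pos - run[-1].pos <= window_bp:
                run.append(k)
            else:
                if len(run) >= min_calls:
                    flagged.update(run)
                run = [k]
        if len(run) >= min_calls:
            flagged.update(run)
    records = {
        k: (replace(r, flags=r.flags | {CLUSTERED_FLAG}) if k in flagged else r)
        for k, r in c.records.items()
    }
    return c.with_records(records)


def drop_flagged(c: CallSet, flag: str = CLUSTERED_FLAG) -> CallSet:
    """Remove records carrying ``flag`` (the paper-style clustered-FP exclusion)."""
    return c.with_records({k: r for k, r in c.records.items() if flag not in r.flags})


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a VAF-cutoff grid calibration against a target FPR."""

    calibrated_vaf_min: float
    achieved_fpr: float
    target_fpr: float
    grid_step: float
    trace: tuple[tuple[float, float], ...]
    attainable: bool = True

    @property
    def profile_of(self) -> float:
        return self.calibrated_vaf_min


def calibrate_vaf_cutoff(
    c: CallSet,
    t: TruthSet,
    base: FilterProfile,
    target_fpr: float,
    grid_step: float = 0.001,
) -> CalibrationResult:
    """Smallest grid VAF cutoff for which the filtered call set's FPR <= target.

    Scans ``base.vaf_min, base.vaf_min + grid_step, ... <= 1.0``; each candidate
    substitutes the cutoff into ``base``, applies the filter and estimates the
    FPR.  If even a cutoff of 1.0 cannot reach the target the result is flagged
    unattainable (and carries the grid maximum).
    """
    if target_fpr < 0:
        raise ValueError("target_fpr must be >= 0")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    denom = t.kn_size
    if denom == 0:
        raise ValueError("calibration undefined: truth set has no KN positions")

    # Records surviving every non-VAF constraint, split by FP status; FPR at
    # cutoff v is then a sorted-array tail count (FPR is a step function of v).
    non_vaf = replace(base, vaf_min=0.0)
    survivors = [r for r in c.records.values() if passes(r, non_vaf)]
    fp_vafs = np.sort(
        [r.vaf for r in survivors if t.classify(r.key) is ClassLabel.FP]
    )

    n_steps = int(np.floor((1.0 - base.vaf_min) / grid_step)) + 1
    grid = np.round(base.vaf_min + grid_step * np.arange(n_steps), 10)
    if grid[-1] < 1.0:
        grid = np.append(grid, 1.0)

    n_fp = len(fp_vafs) - np.searchsorted(fp_vafs, grid, side="left")
    fprs = n_fp / denom * 1_000_000
    trace = tuple(zip((float(g) for g in grid), (float(f) for f in fprs)))

    ok = np.nonzero(fprs <= target_fpr)[0]
    if len(ok):
        i = int(ok[0])
        return CalibrationResult(
            calibrated_vaf_min=float(grid[i]),
            achieved_fpr=float(fprs[i]),
            target_fpr=target_fpr,
            grid_step=grid_step,
            trace=trace,
            attainable=True,
        )
    return CalibrationResult(
        calibrated_vaf_min=float(grid[-1]),
        achieved_fpr=float(fprs[-1]),
        target_fpr=target_fpr,
        grid_step=grid_step,
        trace=trace,
        attainable=False,
    )
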