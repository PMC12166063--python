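"""Hard-threshold filter profiles and the multi-caller consensus rule.

Two named profiles are built in:

* ``non_stringent`` — VAF >= 2%, DP >= 20, ADP >= 2, any single caller.  Used
  when RNA-seq verifies DNA variants and recall is the priority.
* ``stringent_base`` — agreement of at least 2 of 3 callers, VAF >= 2%,
  DP >= 20 and ADP strictly greater than 3 (encoded as ``adp_min=4``).  The
  starting point for FPR-controlled standalone RNA-seq detection; its VAF
  cutoff is then raised by calibration.

All thresholds are inclusive (``>=``); only the stringent ADP rule is "greater
than three", hence the ``adp_min`` of 4.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from .callset import CallRecord, CallSet
from .truth import ClassLabel, TruthSet

__all__ = [
    "FilterProfile",
    "NON_STRINGENT",
    "STRINGENT_BASE",
    "DNA_COMPARISON",
    "passes",
    "apply_filter",
    "threshold_sweep",
    "load_profiles",
]


@dataclass(frozen=True)
class FilterProfile:
    """A bundle of inclusive evidence cutoffs plus a caller-consensus minimum."""

    name: str
    vaf_min: float = 0.0
    dp_min: int = 0
    adp_min: int = 0
    min_callers: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf_min <= 1.0):
            raise ValueError(f"vaf_min must be in [0, 1], got {self.vaf_min}")
        if self.dp_min < 0 or self.adp_min < 0:
            raise ValueError("dp_min and adp_min must be non-negative")
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")

    def with_vaf_min(self, vaf_min: float) -> "FilterProfile":
        return replace(self, vaf_min=vaf_min)


NON_STRINGENT = FilterProfile("non_stringent", vaf_min=0.02, dp_min=20, adp_min=2, min_callers=1)
STRINGENT_BASE = FilterProfile("stringent_base", vaf_min=0.02, dp_min=20, adp_min=4, min_callers=2)
#: profile used for the paired DNA-seq comparison in RNA-unique analysis
DNA_COMPARISON = FilterProfile("dna_comparison", vaf_min=0.02, dp_min=20, adp_min=4, min_callers=2)

_BUILTINS = {p.name: p for p in (NON_STRINGENT, STRINGENT_BASE, DNA_COMPARISON)}


def get_profile(name: str) -> FilterProfile:
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; built-ins: {sorted(_BUILTINS)}") from None


def passes(r: CallRecord, p: FilterProfile) -> bool:
    """True iff the record satisfies every cutoff of the profile."""
    return (
        r.vaf >= p.vaf_min
        and r.dp >= p.dp_min
        and r.adp >= p.adp_min
        and len(r.callers) >= p.min_callers
    )


def apply_filter(c: CallSet, p: FilterProfile) -> CallSet:
    """Subset of ``c`` passing the profile (idempotent)."""
    return c.with_records({k: r for k, r in c.records.items() if passes(r, p)})


def threshold_sweep(
    c: CallSet,
    t: TruthSet,
    vaf_grid: list[float],
    adp_grid: list[int],
    base: FilterProfile,
) -> pd.DataFrame:
    """Count total/KP/FP calls over a grid of (vaf_min, adp_min) substitutions.

    Higher thresholds can only remove calls, so counts are non-increasing
    along each grid axis.
    """
    if not vaf_grid or not adp_grid:
        raise ValueError("vaf_grid and adp_grid must be non-empty")
    labels = {k: t.classify(k) for k in c.records}
    rows = []
    for v in vaf_grid:
        for a in adp_grid:
            prof = replace(base, vaf_min=v, adp_min=a)
            kept = [k for k, r in c.records.items() if passes(r, prof)]
            rows.append(
                {
                    "vaf_min": v,
                    "adp_min": a,
                    "total": len(kept),
                    "kp": sum(labels[k] is ClassLabel.KP for k in kept),
                    "fp": sum(labels[k] is ClassLabel.FP for k in kept),
                }
            )
    return pd.DataFrame(rows)


def load_profiles(path: str | Path) -> dict[str, FilterProfile]:
    """Load named filter profiles from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, spec in raw.items():
        out[name] = FilterProfile(
            name=name,
            vaf_min=float(spec.get("vaf_min", 0.0)),
            dp_min=int(spec.get("dp_min", 0)),
            adp_min=int(spec.get("adp_min", 0)),
            min_callers=int(spec.get("min_callers", 1)),
        )
    return out
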