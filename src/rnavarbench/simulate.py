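"""Seeded synthetic cohort emulating the reference-sample benchmarking design.

The generator reproduces, at desk scale, the statistical structure the
evaluation framework assumes:

* a reference sample built as an equal-mass mixture of ten cell lines, so DNA
  truth VAFs sit on the allele-dosage grid k/20 with a bias toward few
  carrier lines;
* targeted panels of merged exon-sized intervals inside a larger
  high-confidence Consensus Target Region (CTR), optionally overlapping
  between panels;
* an incomplete truth set: known positives with truth VAFs, known-negative
  positions *sampled* at a density below 1 (so genuinely uncharacterized
  calls exist), and hidden true variants absent from both KP and KN — some
  present only in RNA;
* zero-inflated log-normal exon expression, with RNA VAF coupled to DNA VAF
  through a Beta distribution whose concentration controls allele-specific
  expression noise;
* per-replicate sequencing evidence: gamma-Poisson (negative-binomial) depth
  scaled by capture efficiency and (for RNA) expression, binomial
  allele-depth sampling, and sparse low-VAF error events at non-variant
  positions;
* three black-box caller profiles of differing sensitivity (ADP detection
  floor, dropout, caller-private false positives) plus an optional injected
  cluster of co-located high-VAF artifact calls flagged as clustered events.

Everything derives from a single seed; equal seeds give byte-identical
fixtures.  The generator keeps a resolved truth book (true class of every
emitted call, expression truth of every KP) so downstream tests can check
PPV bracketing and missed-call categorisation exactly, not statistically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .callset import Assay, CallRecord, CallSet, merge_callers, restrict_callset
from .expression import ExonRecord, write_exon_table
from .regions import Interval, RegionSet, intersect, write_bed
from .truth import TruthSet, VariantKey, write_kn_bed, write_truth_vcf

__all__ = [
    "PanelSpec",
    "CallerProfile",
    "SimConfig",
    "SimulatedCohort",
    "simulate_truth",
    "simulate_expression",
    "simulate_callsets",
    "simulate_cohort",
    "write_fixture",
]

_BASES = "ACGT"
_CHROM = "chr1"
_EXON_GAP = 100


@dataclass(frozen=True)
class PanelSpec:
    """A targeted panel: a run of exons, optionally overlapping the previous panel."""

    label: str
    n_intervals: int = 8000
    interval_length: int = 250
    overlap_fraction: float = 0.0


@dataclass(frozen=True)
class CallerProfile:
    """Black-box caller emulation: detection floor, dropout, private FPs."""

    name: str
    min_adp_detect: int = 3
    dropout_prob: float = 0.05
    extra_fp_rate: float = 1e-4
    reports_low_adp_fp: bool = False

    def __post_init__(self) -> None:
        if self.min_adp_detect < 1:
            raise ValueError("min_adp_detect must be >= 1")


def default_caller_profiles() -> tuple[CallerProfile, ...]:
    """Sensitive / balanced / conservative profiles (highest FP burden first)."""
    return (
        CallerProfile("sensitive", min_adp_detect=2, dropout_prob=0.02,
                      extra_fp_rate=5e-4, reports_low_adp_fp=True),
        CallerProfile("balanced", min_adp_detect=3, dropout_prob=0.05,
                      extra_fp_rate=1e-4, reports_low_adp_fp=False),
        CallerProfile("conservative", min_adp_detect=4, dropout_prob=0.10,
                      extra_fp_rate=5e-5, reports_low_adp_fp=False),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic cohort (seed-determined)."""

    seed: int = 0
    n_lines: int = 10
    panels: tuple[PanelSpec, ...] = (PanelSpec("panelA"),)
    n_kp: int = 2000
    kn_density: float = 0.5
    n_hidden_true: int = 120
    n_rna_only: int = 40
    indel_fraction: float = 0.1
    common_variant_frac: float = 0.08
    zero_expr_frac: float = 0.3
    expr_logmean: float = 4.0
    expr_logsd: float = 1.2
    depth_mean: float = 300.0
    wts_depth_mean: float = 50.0
    overdispersion: float = 4.0
    capture_logsd: float = 0.4
    ase_concentration: float = 30.0
    base_error: float = 0.005
    dna_error_factor: float = 0.01
    error_vaf_alpha: float = 2.0
    error_vaf_beta: float = 300.0
    caller_dp_floor: int = 10
    caller_profiles: tuple[CallerProfile, ...] = field(default_factory=default_caller_profiles)
    n_replicates: int = 4
    cluster_artifact: bool = True
    cluster_size: int = 10
    include_wts: bool = False

    def __post_init__(self) -> None:
        for name in ("kn_density", "zero_expr_frac", "indel_fraction", "common_variant_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if not self.panels:
            raise ValueError("at least one panel required")
        if self.n_rna_only > self.n_hidden_true:
            raise ValueError("n_rna_only cannot exceed n_hidden_true")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["panels"] = tuple(PanelSpec(**p) for p in d.get("panels", ()))
        d["caller_profiles"] = tuple(
            CallerProfile(**p) for p in d.get("caller_profiles", ())
        ) or default_caller_profiles()
        return cls(**d)


# ---------------------------------------------------------------------------
# stage 1: genome, panels, truth


@dataclass
class _Variant:
    """Internal truth bookkeeping for one simulated variant."""

    key: VariantKey
    exon_idx: int
    dna_vaf: float
    rna_vaf: float = float("nan")
    is_kp: bool = True
    rna_only: bool = False


@dataclass
class SimulatedTruth:
    exon_intervals: list[Interval]
    panel_exons: dict[str, np.ndarray]  # label -> exon indices
    panels: dict[str, RegionSet]
    ctr: RegionSet
    variants: list[_Variant]
    kn: dict[str, np.ndarray]

    def truth_for(self, panel: str) -> TruthSet:
        """Panel-and-CTR-restricted truth set (KP variants + KN positions)."""
        region = intersect(self.panels[panel], self.ctr, label=f"{panel}&CTR")
        kp = {
            v.key: v.dna_vaf
            for v in self.variants
            if v.is_kp and region.contains(v.key.chrom, v.key.pos)
        }
        kn = {}
        for chrom, arr in self.kn.items():
            mask = region.contains_many(chrom, arr)
            if mask.any():
                kn[chrom] = arr[mask]
        return TruthSet(kp=kp, kn=kn, region=region)


def _dosage_vaf(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Mixture-design DNA VAFs on the k/(2*n_lines) dosage grid, few-line biased."""
    common = rng.random(n) < cfg.common_variant_frac
    carriers = np.where(
        common,
        rng.binomial(cfg.n_lines, 0.8, size=n),
        1 + np.minimum(cfg.n_lines - 1, rng.poisson(0.8, size=n)),
    )
    carriers = np.maximum(carriers, 1)
    hom_p = np.where(common, 0.5, 0.1)
    homs = rng.binomial(carriers, hom_p)
    dosage = carriers + homs
    return dosage / (2.0 * cfg.n_lines)


def _ref_at(pos: int) -> str:
    return _BASES[pos % 4]


def _alt_snv(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in _BASES if b != ref]
    return choices[rng.integers(len(choices))]


def simulate_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulatedTruth:
    """Lay out exons and panels, draw KP/hidden variants and sample KN positions."""
    rng = rng if rng is not None else np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    # exon universe: consecutive runs per panel, overlapping the previous panel
    panel_ranges: dict[str, tuple[int, int]] = {}
    cursor = 0
    lengths: list[int] = []
    for spec in cfg.panels:
        n_shared = int(round(spec.overlap_fraction * spec.n_intervals)) if panel_ranges else 0
        start = max(cursor - n_shared, 0)
        end = start + spec.n_intervals
        panel_ranges[spec.label] = (start, end)
        while len(lengths) < end:
            lengths.append(spec.interval_length)
        cursor = end
    n_exons = len(lengths)

    starts = np.concatenate([[0], np.cumsum(np.asarray(lengths) + _EXON_GAP)[:-1]])
    exon_intervals = [
        Interval(_CHROM, int(s), int(s) + L) for s, L in zip(starts, lengths)
    ]
    panels = {
        label: RegionSet([exon_intervals[i] for i in range(a, b)], label=label)
        for label, (a, b) in panel_ranges.items()
    }
    panel_exons = {label: np.arange(a, b) for label, (a, b) in panel_ranges.items()}
    # CTR trims ~1% of exons at each edge of the universe
    trim = max(1, n_exons // 100)
    ctr = RegionSet(exon_intervals[trim : n_exons - trim], label="CTR")

    # variant placement over CTR exons, length-weighted, distinct loci
    ctr_lo, ctr_hi = trim, n_exons - trim
    ctr_idx = np.arange(ctr_lo, ctr_hi)
    weights = np.asarray([lengths[i] for i in ctr_idx], dtype=float)
    n_total = cfg.n_kp + cfg.n_hidden_true
    if weights.sum() < n_total * 4:
        raise ValueError("region too small for the requested number of variants")
    probs = weights / weights.sum()

    taken: set[int] = set()
    placements: list[tuple[int, int]] = []  # (exon_idx, 1-based pos)
    while len(placements) < n_total:
        draw = n_total - len(placements)
        ex = rng.choice(ctr_idx, size=draw * 2, p=probs)
        off = rng.integers(0, [lengths[i] for i in ex])
        for e, o in zip(ex, off):
            pos = exon_intervals[e].start + int(o) + 1  # 1-based
            if pos not in taken:
                taken.add(pos)
                placements.append((int(e), pos))
                if len(placements) == n_total:
                    break

    dna_vafs = _dosage_vaf(rng, cfg, n_total)
    is_indel = rng.random(n_total) < cfg.indel_fraction
    variants: list[_Variant] = []
    for i, (e, pos) in enumerate(placements):
        ref = _ref_at(pos)
        if is_indel[i]:
            k = int(rng.integers(1, 5))
            ins = "".join(_BASES[j] for j in rng.integers(0, 4, size=k))
            if rng.random() < 0.5:
                alt = ref + ins
            else:
                ref, alt = ref + ins, ref
        else:
            alt = _alt_snv(rng, ref)
        is_kp = i < cfg.n_kp
        rna_only = (not is_kp) and (i >= n_total - cfg.n_rna_only)
        variants.append(
            _Variant(
                key=VariantKey(_CHROM, pos, ref, alt),
                exon_idx=e,
                dna_vaf=0.0 if rna_only else float(dna_vafs[i]),
                is_kp=is_kp,
                rna_only=rna_only,
            )
        )

    # KN positions: sampled at kn_density over CTR bases, excluding variant loci
    kn_parts = []
    for i in ctr_idx:
        iv = exon_intervals[i]
        base = np.arange(iv.start + 1, iv.end + 1, dtype=np.int64)  # 1-based
        kn_parts.append(base[rng.random(len(base)) < cfg.kn_density])
    kn_all = np.concatenate(kn_parts) if kn_parts else np.empty(0, dtype=np.int64)
    loci = np.fromiter((v.key.pos for v in variants), dtype=np.int64)
    kn_all = kn_all[~np.isin(kn_all, loci)]
    return SimulatedTruth(
        exon_intervals=exon_intervals,
        panel_exons=panel_exons,
        panels=panels,
        ctr=ctr,
        variants=variants,
        kn={_CHROM: kn_all},
    )


# ---------------------------------------------------------------------------
# stage 2: expression and RNA VAF


def simulate_expression(
    cfg: SimConfig, truth: SimulatedTruth, rng: np.random.Generator | None = None
) -> list[ExonRecord]:
    """Zero-inflated log-normal exon counts; fills each variant's RNA VAF.

    An unexpressed exon (probability ``zero_expr_frac``) has count 0 and its
    variants carry no RNA signal.  For expressed KP/hidden variants the RNA
    VAF is Beta-distributed with mean equal to the DNA VAF and concentration
    ``ase_concentration``; RNA-only variants draw their level from the same
    mixture-dosage grid used for DNA.
    """
    rng = rng if rng is not None else np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = len(truth.exon_intervals)
    expressed = rng.random(n) >= cfg.zero_expr_frac
    counts = np.where(
        expressed,
        np.maximum(1, np.round(rng.lognormal(cfg.expr_logmean, cfg.expr_logsd, size=n))),
        0,
    ).astype(int)
    exons = [
        ExonRecord(f"exon{i:06d}", iv, int(counts[i]))
        for i, iv in enumerate(truth.exon_intervals)
    ]
    c = cfg.ase_concentration
    for v in truth.variants:
        if counts[v.exon_idx] == 0:
            v.rna_vaf = float("nan")
            continue
        if v.rna_only:
            v.rna_vaf = float(_dosage_vaf(rng, cfg, 1)[0])
        else:
            m = min(max(v.dna_vaf, 1e-3), 1 - 1e-3)
            v.rna_vaf = float(rng.beta(m * c, (1 - m) * c))
    return exons


# ---------------------------------------------------------------------------
# stage 3: per-replicate, per-caller call lists


def _nb_depth(rng: np.random.Generator, mean: np.ndarray, od: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) depths with dispersion ``od``."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    return rng.poisson(rng.gamma(od, mean / od))


@dataclass
class SimulatedCalls:
    """Per (panel, assay, replicate) -> caller name -> list of CallRecord."""

    calls: dict[tuple[str, str, str], dict[str, list[CallRecord]]]
    #: resolved truth of every emitted call key: True (real variant) / False (error)
    resolved: dict[VariantKey, bool]


def simulate_callsets(
    cfg: SimConfig,
    truth: SimulatedTruth,
    exons: list[ExonRecord],
    rng: np.random.Generator | None = None,
) -> SimulatedCalls:
    rng = rng if rng is not None else np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    counts = np.asarray([e.count for e in exons], dtype=float)
    mean_count = float(np.exp(cfg.expr_logmean + cfg.expr_logsd**2 / 2))
    expr_scale = np.clip(counts / mean_count, 0.0, 10.0)

    # per-panel, per-exon capture efficiency (bait performance)
    capture = {
        label: rng.lognormal(0.0, cfg.capture_logsd, size=len(exons))
        for label in truth.panels
    }

    loci = np.fromiter((v.key.pos for v in truth.variants), dtype=np.int64)
    locus_set = set(int(p) for p in loci)

    assays = [Assay.DNA, Assay.RNA] + ([Assay.WTS] if cfg.include_wts else [])
    calls: dict[tuple[str, str, str], dict[str, list[CallRecord]]] = {}
    resolved: dict[VariantKey, bool] = {}

    for label, region_exons in truth.panel_exons.items():
        region = intersect(truth.panels[label], truth.ctr)
        region_size = region.total_size
        in_region = [
            v for v in truth.variants if region.contains(v.key.chrom, v.key.pos)
        ]
        # flat arrays of candidate region positions for error events
        exon_arr = [truth.exon_intervals[i] for i in region_exons]
        pos_pool = np.concatenate(
            [np.arange(iv.start + 1, iv.end + 1, dtype=np.int64) for iv in exon_arr]
        )
        pool_mask = region.contains_many(_CHROM, pos_pool)
        pos_pool = pos_pool[pool_mask]
        pool_exon = np.concatenate(
            [np.full(iv.size, i) for i, iv in zip(region_exons, exon_arr)]
        )[pool_mask]

        for assay in assays:
            for rep in range(cfg.n_replicates):
                rep_id = f"rep{rep + 1}"
                per_caller: dict[str, list[CallRecord]] = {
                    p.name: [] for p in cfg.caller_profiles
                }

                # --- evidence at true-variant sites -------------------------
                site_keys: list[VariantKey] = []
                site_vaf: list[float] = []
                site_mean: list[float] = []
                for v in in_region:
                    tv = v.dna_vaf if assay is Assay.DNA else v.rna_vaf
                    if not np.isfinite(tv) or tv <= 0:
                        continue
                    if assay is Assay.DNA:
                        m = cfg.depth_mean * capture[label][v.exon_idx]
                    elif assay is Assay.RNA:
                        m = cfg.depth_mean * capture[label][v.exon_idx] * expr_scale[v.exon_idx]
                    else:
                        m = cfg.wts_depth_mean * expr_scale[v.exon_idx]
                    site_keys.append(v.key)
                    site_vaf.append(tv)
                    site_mean.append(m)

                # --- sparse error events at non-variant positions -----------
                # DNA libraries skip the RT step, so their error-event rate is
                # a configured fraction of the RNA rate.
                err_rate = cfg.base_error * (
                    cfg.dna_error_factor if assay is Assay.DNA else 1.0
                )
                n_err = rng.binomial(region_size, err_rate)
                err_idx = rng.choice(len(pos_pool), size=n_err, replace=False)
                err_pos = pos_pool[err_idx]
                err_exon = pool_exon[err_idx]
                keep = ~np.isin(err_pos, loci)
                err_pos, err_exon = err_pos[keep], err_exon[keep]
                err_vafs = rng.beta(cfg.error_vaf_alpha, cfg.error_vaf_beta, size=len(err_pos))
                for p, e, ev in zip(err_pos, err_exon, err_vafs):
                    ref = _ref_at(int(p))
                    key = VariantKey(_CHROM, int(p), ref, _alt_snv(rng, ref))
                    if assay is Assay.DNA:
                        m = cfg.depth_mean * capture[label][e]
                    elif assay is Assay.RNA:
                        m = cfg.depth_mean * capture[label][e] * expr_scale[e]
                    else:
                        m = cfg.wts_depth_mean * expr_scale[e]
                    site_keys.append(key)
                    site_vaf.append(float(ev))
                    site_mean.append(m)

                dp = _nb_depth(rng, np.asarray(site_mean), cfg.overdispersion)
                adp = rng.binomial(dp, np.asarray(site_vaf))

                detectable = (adp >= 1) & (dp >= cfg.caller_dp_floor)
                for prof in cfg.caller_profiles:
                    drop = rng.random(len(dp)) < prof.dropout_prob
                    rep_mask = detectable & (adp >= prof.min_adp_detect) & ~drop
                    recs = per_caller[prof.name]
                    for i in np.nonzero(rep_mask)[0]:
                        recs.append(
                            CallRecord(
                                key=site_keys[i],
                                vaf=float(adp[i] / dp[i]),
                                dp=int(dp[i]),
                                adp=int(adp[i]),
                                callers=frozenset({prof.name}),
                            )
                        )

                for k in site_keys:
                    resolved.setdefault(k, int(k.pos) in locus_set)

                # --- caller-private low-evidence FPs ------------------------
                for prof in cfg.caller_profiles:
                    n_priv = rng.poisson(prof.extra_fp_rate * region_size)
                    if n_priv == 0:
                        continue
                    idx = rng.choice(len(pos_pool), size=n_priv, replace=False)
                    ppos = pos_pool[idx]
                    ppos = ppos[~np.isin(ppos, loci)]
                    p_adp = 2 if prof.reports_low_adp_fp else prof.min_adp_detect
                    p_dp = np.maximum(_nb_depth(rng, np.full(len(ppos), 80.0), cfg.overdispersion), p_adp)
                    for p, d in zip(ppos, p_dp):
                        ref = _ref_at(int(p))
                        key = VariantKey(_CHROM, int(p), ref, _alt_snv(rng, ref))
                        per_caller[prof.name].append(
                            CallRecord(
                                key=key,
                                vaf=float(p_adp / d),
                                dp=int(d),
                                adp=int(p_adp),
                                callers=frozenset({prof.name}),
                            )
                        )
                        resolved.setdefault(key, False)

                # --- injected clustered artifact ----------------------------
                first_panel = next(iter(truth.panels))
                if (
                    cfg.cluster_artifact
                    and label == first_panel
                    and assay is Assay.RNA
                    and rep == 0
                ):
                    for rec in _cluster_records(cfg, truth, region, rng):
                        per_caller[cfg.caller_profiles[0].name].append(rec)
                        per_caller[cfg.caller_profiles[1].name].append(
                            dataclasses.replace(rec, flags=frozenset({"clustered_events"}))
                        )
                        resolved.setdefault(rec.key, False)

                calls[(label, assay.value, rep_id)] = per_caller
    return SimulatedCalls(calls=calls, resolved=resolved)


def _cluster_records(
    cfg: SimConfig, truth: SimulatedTruth, region: RegionSet, rng: np.random.Generator
) -> list[CallRecord]:
    """~10 co-located high-VAF artifact calls at KN positions in one window."""
    kn = truth.kn[_CHROM]
    kn_in = kn[region.contains_many(_CHROM, kn)]
    n = cfg.cluster_size
    # first run of n KN positions spanning <= 150 bp
    for i in range(len(kn_in) - n):
        if kn_in[i + n - 1] - kn_in[i] <= 150:
            window = kn_in[i : i + n]
            break
    else:  # pragma: no cover - dense KN makes this unreachable in practice
        raise RuntimeError("no KN window available for cluster artifact")
    out = []
    for p in window:
        ref = _ref_at(int(p))
        vaf = float(rng.uniform(0.15, 0.35))
        dp = int(max(50, _nb_depth(rng, np.asarray([300.0]), cfg.overdispersion)[0]))
        adp = max(1, round(vaf * dp))
        out.append(
            CallRecord(
                key=VariantKey(_CHROM, int(p), ref, _alt_snv(rng, ref)),
                vaf=adp / dp,
                dp=dp,
                adp=adp,
                callers=frozenset({cfg.caller_profiles[0].name}),
            )
        )
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedCohort:
    """A fully simulated study: regions, truth, expression, multi-caller calls."""

    cfg: SimConfig
    truth: SimulatedTruth
    exons: list[ExonRecord]
    sim_calls: SimulatedCalls

    @property
    def panel_labels(self) -> list[str]:
        return list(self.truth.panels)

    def truth_for(self, panel: str) -> TruthSet:
        return self.truth.truth_for(panel)

    def analysis_region(self, panel: str) -> RegionSet:
        return intersect(self.truth.panels[panel], self.truth.ctr, label=f"{panel}&CTR")

    def per_caller(self, panel: str, assay: Assay, rep_id: str) -> dict[str, list[CallRecord]]:
        return self.sim_calls.calls[(panel, assay.value, rep_id)]

    def replicate_ids(self) -> list[str]:
        return [f"rep{i + 1}" for i in range(self.cfg.n_replicates)]

    def merged_callset(self, panel: str, assay: Assay, rep_id: str) -> CallSet:
        """Multi-caller merged call set restricted to panel & CTR."""
        merged = merge_callers(
            self.per_caller(panel, assay, rep_id),
            panel_id=panel,
            replicate_id=rep_id,
            assay=assay,
            priority=[p.name for p in self.cfg.caller_profiles],
        )
        return restrict_callset(merged, self.analysis_region(panel))

    def is_true_call(self, key: VariantKey) -> bool:
        """Resolved truth of an emitted call (KP or hidden true vs error)."""
        return self.sim_calls.resolved.get(key, False)

    def unexpressed_kp_keys(self, panel: str) -> set[VariantKey]:
        region = self.analysis_region(panel)
        return {
            v.key
            for v in self.truth.variants
            if v.is_kp
            and not np.isfinite(v.rna_vaf)
            and region.contains(v.key.chrom, v.key.pos)
        }


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Run all generator stages from the single root seed."""
    truth = simulate_truth(cfg)
    exons = simulate_expression(cfg, truth)
    sim_calls = simulate_callsets(cfg, truth, exons)
    return SimulatedCohort(cfg=cfg, truth=truth, exons=exons, sim_calls=sim_calls)


# ---------------------------------------------------------------------------
# fixture output


def _caller_vcf_header() -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(_CHROM, length=2**29)
    header.info.add("DP", 1, "Integer", "Total read depth")
    header.info.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.info.add("AF", "A", "Float", "Allele fraction")
    header.filters.add("clustered_events", None, None, "Clustered events artifact")
    return header


def write_fixture(cohort: SimulatedCohort, out_dir: str | Path) -> list[Path]:
    """Write the cohort as plain-text files (BED, VCF, TSV, JSON); returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _note(p: Path) -> Path:
        written.append(p)
        return p

    for label, region in cohort.truth.panels.items():
        write_bed(region, _note(out / f"panel_{label}.bed"))
    write_bed(cohort.truth.ctr, _note(out / "ctr.bed"))
    write_kn_bed(cohort.truth.kn, _note(out / "kn.bed"))
    ctr_truth = TruthSet(
        kp={v.key: v.dna_vaf for v in cohort.truth.variants if v.is_kp},
        kn={},
        region=cohort.truth.ctr,
    )
    write_truth_vcf(ctr_truth, _note(out / "truth_kp.vcf"))
    write_exon_table(cohort.exons, _note(out / "exons.tsv"))
    cohort.cfg.to_json(_note(out / "simconfig.json"))

    for (label, assay, rep_id), per_caller in sorted(cohort.sim_calls.calls.items()):
        for caller, records in per_caller.items():
            path = _note(out / f"calls_{label}_{assay}_{rep_id}_{caller}.vcf")
            with pysam.VariantFile(str(path), "w", header=_caller_vcf_header()) as vcf:
                for rec in sorted(records, key=lambda r: r.key):
                    v = vcf.new_record(
                        contig=rec.key.chrom,
                        start=rec.key.pos - 1,
                        alleles=(rec.key.ref, rec.key.alt),
                    )
                    v.info["DP"] = rec.dp
                    v.info["AD"] = (rec.dp - rec.adp, rec.adp)
                    v.info["AF"] = rec.vaf
                    if "clustered_events" in rec.flags:
                        v.filter.add("clustered_events")
                    vcf.write(v)
    return written
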