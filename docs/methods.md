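# Methods

## Truth model and classification

The framework assumes a reference sample whose ground truth is *incomplete*:
a set of known-positive variants (KP, each with a truth VAF) and a set of
known-negative positions (KN), both valid only inside a high-confidence
Consensus Target Region (CTR). Every analysis first restricts call sets and
truth to panel ∩ CTR.

A call is classified by identity: KP on an exact (chrom, pos, ref, alt)
match; FP if its anchor position is KN — a KN position is negative for
*every* alternative allele, and an indel anchored at a KN position is FP
unless it is itself a KP key; otherwise uncharacterized. Multi-allelic
records are split so each alt allele is a distinct identity; SNVs and small
indels (ref/alt length difference ≤ 5) are analysed together, larger events
are dropped at parse time. Classification raises on keys outside the truth
region rather than guessing.

The estimated false-positive rate is

    FPR = (# calls at KN positions) / (# KN positions) × 1,000,000

Uncharacterized calls never enter the numerator, so the estimate is
conservative by construction.

PPV is bracketed rather than computed: the upper bound counts
uncharacterized calls as true positives, the lower bound as negatives. On
simulated cohorts, where the generator retains the true class of every
emitted call, the resolved PPV provably falls inside the bracket; a
dedicated test checks this over 100 seeds.

## Filter profiles and VAF-cutoff calibration

Two built-in profiles encode the two operating points:

| profile | VAF | DP | ADP | callers |
|---|---|---|---|---|
| `non_stringent` | ≥ 2% | ≥ 20 | ≥ 2 | ≥ 1 |
| `stringent_base` | ≥ 2% | ≥ 20 | > 3 (i.e. ≥ 4) | ≥ 2 of 3 |

All thresholds are inclusive except the stringent ADP rule, which is
"greater than three" and therefore encoded as `adp_min = 4`. VAF is stored
as a fraction throughout and compared without pre-rounding; grid cutoffs are
rounded at 10 decimals to suppress float accumulation.

Calibration raises `vaf_min` of a base profile over a regular grid (default
step 0.001 on the fraction) and returns the *smallest* cutoff whose filtered
call set has FPR ≤ target, together with the full (cutoff, FPR) trace. A
grid rather than bisection because FPR is a step function of the cutoff:
minimality is then directly checkable by exhaustive re-scan, and the
granularity matches how panel-specific cutoffs are usually reported (e.g.
3.7%, 5.7%). If even a cutoff of 1.0 misses the target the result is flagged
unattainable instead of being silently clamped. Set-points: 50 FP/Mb when
RNA-seq is used to verify DNA variants, 5 FP/Mb for standalone detection.
Calibration is per replicate; panel summaries report the mean cutoff and
mean achieved FPR over replicates.

Clustered artifacts — runs of co-located calls that are a known ensemble
failure mode — are flagged by single-linkage chaining (defaults: window
200 bp, minimum run 5) and excluded before standalone calibration. The
defaults are explicit configuration so the exclusion is reproducible.

## Reproducibility and concordance

Reproducibility between replicates is directional: the fraction of LibA's
final calls whose identity appears in LibB. A hard VAF cutoff induces a
boundary effect (a variant at 3.8% in LibA and 3.6% in LibB under a 3.7%
cutoff would spuriously count as irreproducible), so membership in the
partner library is tested after relaxing the partner's cutoff to the 2% VAF
floor. Four replicates yield 12 directed values; the mean is the summary
statistic. Only call identity is compared, not evidence agreement.

VAF concordance between two call sets (or a call set and the truth VAFs) is
ordinary least squares over shared keys, complete-case; R² is reported for
VAF and for log2 depth (pairs with either depth zero are dropped, and a
degenerate spread yields an undefined R² rather than a fabricated one).

## Triage taxonomies

Both taxonomies are ordered, short-circuit evaluations, so category counts
partition their input sets and percentages sum to 100.

Missed KPs (under the non-stringent profile): **not expressed** (smallest
covering exon has zero reads, or no caller produced any evidence) → **low
VAF** (< 2%) → **low DP** (< 20) → **low ADP** (< 2). Evidence passing all
thresholds contradicts "missed" and raises. Variant expression is the read
count of the smallest exon covering the variant position (ties broken by
smaller start, then exon id); a variant covered by no exon counts as zero.
This operationalisation conflates true transcriptional silence with poor
bait performance — a documented caveat, not distinguishable from count data.

Panel-unique variants (present in panel X's final overlap-region calls,
absent from panel Y's): **no caller** reported it in Y → **one caller
only** → **failed Y's calibrated VAF cutoff** (≥ 2 callers, VAF below) →
**other filter** (DP or ADP). "Other filter" is defined here as DP/ADP
failure since the remaining constraints are exactly those two.

RNA-unique variants are per-replicate set differences keys(RNA_i) \
keys(DNA_i), unioned with provenance, after clustered-call exclusion; the
paired DNA call sets use the fixed stringent DNA profile (VAF ≥ 2%, ADP ≥ 4,
DP ≥ 20, 2-of-3 callers).

Merged-library analysis is evidence-level: shared keys sum DP and ADP, VAF
is recomputed as ADP'/DP', caller sets union. This preserves the
depth-doubling effect of pooling two libraries without requiring read-level
data; it does not re-run callers on merged alignments.

## Synthetic cohort generator

The generator emulates the reference-sample design end to end so the
framework can be exercised and unit-tested without sequencing data. All
randomness derives from one root seed (NumPy `SeedSequence`); equal seeds
give byte-identical fixtures.

**Genome and panels.** Exon-sized intervals (default 250 bp, 100 bp gaps)
tile one synthetic chromosome; each panel is a run of exons, optionally
overlapping the previous panel; the CTR trims ~1% of exons at each edge so
region restriction is a real operation. The default configuration is one
panel of 8,000 exons (2.0 Mb), four replicate libraries.

**Truth.** DNA truth VAFs follow the equal-mass ten-line mixture: carriers
drawn with a few-line bias (1 + Poisson(0.8), with an 8% "common variant"
component carried by most lines), heterozygous with 10% (50% for common)
homozygosity, giving dosage/(2·10) values on the k/20 grid dominated by the
0.05 level. 2,000 KPs by default; 90% SNVs, 10% indels ≤ 5 bp. KN positions
are *sampled* at density 0.5 over CTR bases not hosting variants (~1 M KN),
mirroring truth incompleteness and producing genuinely uncharacterized
calls. In addition, 120 hidden true variants (absent from KP and KN, 40 of
them RNA-only) make the uncharacterized class contain real positives, so
the PPV bracket is non-degenerate and RNA-unique discovery has signal.

**Expression and allele-specific noise.** Each exon is unexpressed with
probability 0.3, else its count is log-normal (log-mean 4.0, log-sd 1.2).
For expressed variants the RNA VAF is Beta-distributed with mean equal to
the DNA VAF and concentration 30 — chosen by a calibration sweep so the
regression R² of RNA on DNA VAF lands in the ≈ 0.85 regime reported for
this assay class; it is a tuning knob, not a biological claim.

**Sequencing evidence.** Site depth is gamma-Poisson (negative binomial,
dispersion 4) with mean 300 × capture-efficiency (per panel × exon,
log-normal sd 0.4) × expression scaling for RNA (count / mean count, capped
at 10; zero for unexpressed exons). ADP is Binomial(DP, VAF); reported VAF
is ADP/DP. Error evidence at non-variant positions uses a two-stage model:
each region base independently hosts an error *event* with probability
0.005 per RNA replicate (1% of that for DNA, whose library preparation
skips reverse transcription), and event sites draw an error allele fraction
from Beta(2, 300) (mean ≈ 0.7%) before binomial sampling. The event-rate ×
low-fraction decomposition reproduces the observed regime — false positives
concentrated at VAF ≤ 5%, consensus-profile FPR of order tens per million
KN bases before calibration, calibrated cutoffs landing near 3–6% — while
keeping a million-KN cohort generatable in seconds; a single per-read error
rate at these depths cannot do both.

**Callers.** Three black-box profiles: *sensitive* (detects ADP ≥ 2, 2%
dropout, the largest private-FP rate, and reports low-ADP error sites),
*balanced* (ADP ≥ 3, 5% dropout), *conservative* (ADP ≥ 4, 10% dropout).
Caller-private FPs are emitted with ADP 2 at lower coverage (mean 80),
mimicking the single-caller low-evidence FP class; they pass the
non-stringent profile and die under consensus. One replicate receives an
injected cluster of 10 co-located high-VAF (15–35%) artifact calls at KN
positions, reported by two callers and flagged `clustered_events` — the
motivation for the clustered-call exclusion step. Callers also require
DP ≥ 10 to report at all, so very shallow sites yield no evidence.

**Bookkeeping.** The generator retains the true class of every emitted call
and the expression truth of every KP, enabling exact (non-statistical)
tests: the resolved PPV must fall inside the reported bracket, and the
not-expressed missed-KP category must recover the generator's unexpressed
subset exactly.

## Problem sizes and runtime

The full-scale cohort used by the tests and by `scripts/acceptance.py` (one
2 Mb panel, ~1 M KN positions, ~2,000 KPs, 4 replicates, 3 callers, RNA +
DNA) generates in ~2 s and a complete scenario run finishes in seconds on a
single core; the whole test suite, including 100 seeded bracketing runs and
the brute-force oracle comparisons, runs in well under a minute. Two-panel
configurations used for overlap comparison halve the per-panel size.

## Numerical conventions and degenerate inputs

* BED intervals are 0-based half-open; VCF positions 1-based. Conversion
  happens only inside point-membership and restriction operations.
* Touching intervals merge; region size counts each base once.
* Chromosome names compare as exact strings (single reference build
  assumed).
* Caller disagreement on evidence is resolved by a configurable priority
  order (default: the configured caller order), emulating an ensemble
  pipeline that emits one consensus record; the caller membership set is
  always the union.
* Empty denominators (no KN positions, no truth KPs, empty call sets,
  degenerate variance) raise or report NaN explicitly; nothing is silently
  zero-filled.
* Records whose reported VAF disagrees with ADP/DP by more than 0.02 are
  rejected as inconsistent at construction.

## Limitations

* Callers are emulated as thresholds with dropout, not re-implemented;
  conclusions about specific real callers do not transfer.
* No read-level simulation: no alignment artifacts, strand bias, splice
  junctions, RNA editing or fusion transcripts; merged libraries are
  approximated at evidence level.
* Expression-based triage cannot distinguish unexpressed variants from
  capture failures.
* The synthetic error model is stationary across the genome except for
  the injected cluster; real panels show locus-specific artifact
  structure.
* Truth VAFs are used for concordance only, never for classification.
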