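import numpy as np
import pytest

from rnavarbench.callset import Assay, CallRecord, CallSet
from rnavarbench.regions import Interval, RegionSet
from rnavarbench.simulate import PanelSpec, SimConfig, simulate_cohort
from rnavarbench.truth import TruthSet, VariantKey


def make_key(pos: int, chrom: str = "chr1", ref: str = "A", alt: str = "C") -> VariantKey:
    return VariantKey(chrom, pos, ref, alt)


def make_record(
    pos: int,
    vaf: float = 0.05,
    dp: int = 100,
    adp: int | None = None,
    callers=("c1",),
    chrom: str = "chr1",
    ref: str = "A",
    alt: str = "C",
    flags=(),
) -> CallRecord:
    if adp is None:
        adp = round(vaf * dp)
    return CallRecord(
        key=VariantKey(chrom, pos, ref, alt),
        vaf=vaf,
        dp=dp,
        adp=adp,
        callers=frozenset(callers),
        flags=frozenset(flags),
    )


def make_callset(records, panel="p", rep="rep1", assay=Assay.RNA) -> CallSet:
    return CallSet(panel, rep, assay, {r.key: r for r in records})


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Two small overlapping panels; a desk-scale version of the study design."""
    return SimConfig(
        seed=7,
        panels=(
            PanelSpec("pA", n_intervals=400, interval_length=200),
            PanelSpec("pB", n_intervals=400, interval_length=200, overlap_fraction=0.5),
        ),
        n_kp=150,
        n_hidden_true=30,
        n_rna_only=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture()
def toy_truth() -> TruthSet:
    """20 KP SNVs on a 10 kb region with KN at every 10th position."""
    region = RegionSet([Interval("chr1", 0, 10_000)], label="toy")
    kp = {make_key(pos=100 * i + 1, alt="T"): 0.05 * (1 + i % 4) for i in range(20)}
    kp_loci = {k.pos for k in kp}
    kn = np.array([p for p in range(10, 10_000, 10) if p not in kp_loci], dtype=np.int64)
    return TruthSet(kp=kp, kn={"chr1": kn}, region=region)
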