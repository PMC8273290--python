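"""Haplotype-mode DMR calling between samples or groups.

A candidate region is compared between groups through its methylation
haplotype modes. Identical modes mean no DMR, without any testing.
Otherwise the methylation haplotype difference

    MHD(gi, gj) = max(|MH(gi1) - MH(gj1)|, |MH(gi2) - MH(gj2)|)

aligns the higher-MH haplotypes with each other and the lower-MH ones
with each other, and takes the larger absolute MH difference. For more
than two groups the difference is the maximum MHD over group pairs.

Significance is assessed by a read-label permutation test: reads of the
two compared samples are pooled, reassigned to pseudo-samples of the
original sizes, haplotype pairs rebuilt and MHD recomputed; the p-value
is (1 + #{permuted MHD >= observed}) / (1 + n_perm). A region is a DMR
when MHD > 0.5 and p < 0.05 (defaults), and DMRs are classified into
four mode-change types:

1. hypomethylation mode (contains L) vs non-hypomethylation mode;
2. consistent LL vs semi-hypomethylated (contains L, not LL);
3. consistent HH vs semi-hypermethylated (contains H, not HH);
4. any other differing mode pair;

with precedence 1 > 2 > 3 > 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from methap.genome_regions import CandidateRegion
from methap.haplotypes import (
    HaplotypePair,
    build_haplotype_pair,
    is_valid_pair,
    label,
    mhm,
)
from methap.methylation_calls import ReadCallSet

__all__ = [
    "GroupHaplotypeSummary",
    "DmrRecord",
    "group_summary",
    "mhd",
    "multi_group_mhd",
    "region_p_value",
    "call_dmrs",
    "classify_dmr",
    "write_dmr_table",
]

DEFAULT_MHD_MIN = 0.5
DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 200


@dataclass(frozen=True)
class GroupHaplotypeSummary:
    """Per-region MH of a group's higher- and lower-MH haplotypes.

    For multi-sample groups, ``hi``/``lo`` are means over the samples'
    per-pair higher/lower MH values.
    """

    group_id: str
    hi: float
    lo: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.hi <= 1.0):
            raise ValueError("need 0 <= lo <= hi <= 1")

    @property
    def mode(self) -> str:
        """MHM implied by the summary MH values (exact for 1-sample groups)."""
        return _label_of_mh(self.hi) + _label_of_mh(self.lo)


def _label_of_mh(mh: float) -> str:
    if mh <= 0.25:
        return "L"
    if mh <= 0.5:
        return "N"
    if mh <= 0.75:
        return "M"
    return "H"


def group_summary(
    group_id: str, pairs: Sequence[HaplotypePair]
) -> GroupHaplotypeSummary | None:
    """Summarise a group's valid pairs for one region; None if it has none."""
    valid = [p for p in pairs if is_valid_pair(p)]
    if not valid:
        return None
    his, los = zip(*(p.hi_lo for p in valid))
    return GroupHaplotypeSummary(
        group_id=group_id, hi=float(np.mean(his)), lo=float(np.mean(los))
    )


def mhd(gi: GroupHaplotypeSummary, gj: GroupHaplotypeSummary) -> float:
    """Methylation haplotype difference between two groups on one region."""
    return max(abs(gi.hi - gj.hi), abs(gi.lo - gj.lo))


def multi_group_mhd(groups: Sequence[GroupHaplotypeSummary]) -> float:
    """Maximum MHD over all unordered group pairs."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    return max(
        mhd(groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    )


def _pair_mhd(a: HaplotypePair | None, b: HaplotypePair | None) -> float | None:
    """MHD between two single-sample pairs; None if either is missing/invalid."""
    if a is None or b is None or not is_valid_pair(a) or not is_valid_pair(b):
        return None
    sa = GroupHaplotypeSummary("a", *a.hi_lo)
    sb = GroupHaplotypeSummary("b", *b.hi_lo)
    return mhd(sa, sb)


def region_p_value(
    reads_a: ReadCallSet,
    reads_b: ReadCallSet,
    observed_mhd: float,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    th_dp: int = 10,
) -> tuple[float, bool]:
    """Read-label permutation p-value for one region's MHD.

    Pools the two samples' reads, reassigns them to pseudo-samples of the
    original sizes, rebuilds both haplotype pairs and recomputes MHD for
    each of ``n_perm`` permutations. Permutations where either
    pseudo-sample yields no valid pair score MHD 0. Returns (p, degenerate):
    when the pooled reads cannot form valid pairs at all the p-value is 1
    with the degenerate flag set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = list(reads_a.reads) + list(reads_b.reads)
    n_a = len(reads_a.reads)
    n_cpg = reads_a.n_cpg
    if n_a == 0 or len(reads_b.reads) == 0:
        return 1.0, True
    n_exceed = 0
    any_valid = False
    order = np.arange(len(pooled))
    for _ in range(n_perm):
        rng.shuffle(order)
        pseudo_a = ReadCallSet(region_id=reads_a.region_id, n_cpg=n_cpg)
        pseudo_b = ReadCallSet(region_id=reads_b.region_id, n_cpg=n_cpg)
        pseudo_a.reads = [pooled[k] for k in order[:n_a]]
        pseudo_b.reads = [pooled[k] for k in order[n_a:]]
        pa = build_haplotype_pair(pseudo_a, th_dp=th_dp)
        pb = build_haplotype_pair(pseudo_b, th_dp=th_dp)
        perm_mhd = _pair_mhd(pa, pb)
        if perm_mhd is None:
            perm_mhd = 0.0
        else:
            any_valid = True
        if perm_mhd >= observed_mhd:
            n_exceed += 1
    p = (1 + n_exceed) / (1 + n_perm)
    if not any_valid and n_exceed == 0:
        return 1.0, True
    return p, False


@dataclass(frozen=True)
class DmrRecord:
    """Per-region DMR decision between two groups."""

    region_id: str
    chrom: str
    start: int
    end: int
    mhm_a: str
    mhm_b: str
    mhd: float | None
    p_value: float | None
    is_dmr: bool
    dmr_type: int | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.is_dmr:
            assert self.p_value is not None and self.mhd is not None
            assert self.dmr_type is not None


def classify_dmr(mhm_i: str, mhm_j: str) -> tuple[int, str] | None:
    """Four-type classification of a differing MHM pair; None if identical.

    Precedence 1 > 2 > 3 > 4 resolves overlaps (e.g. HL vs HH satisfies
    the surface reading of both rules 1 and 3, and is Type 1).
    """
    if mhm_i == mhm_j:
        return None
    subtype = f"{mhm_i} vs {mhm_j}"
    li, lj = "L" in mhm_i, "L" in mhm_j
    if li != lj:
        return 1, subtype
    for a, b in ((mhm_i, mhm_j), (mhm_j, mhm_i)):
        if a == "LL" and "L" in b and b != "LL":
            return 2, subtype
    for a, b in ((mhm_i, mhm_j), (mhm_j, mhm_i)):
        if a == "HH" and "H" in b and b != "HH":
            return 3, subtype
    return 4, subtype


def call_dmrs(
    regions: Sequence[CandidateRegion],
    calls_a: Mapping[str, ReadCallSet],
    calls_b: Mapping[str, ReadCallSet],
    mhd_min: float = DEFAULT_MHD_MIN,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    th_dp: int = 10,
) -> list[DmrRecord]:
    """Two-sample DMR calling over candidate regions.

    Regions lacking a valid pair in either sample are skipped. Identical
    MHMs are reported as non-DMRs without testing. Otherwise a region is
    a DMR when MHD > ``mhd_min`` and the permutation p-value < ``alpha``;
    the permutation test is only run when the MHD threshold is met.
    """
    rng = np.random.default_rng(seed)
    records: list[DmrRecord] = []
    for region in regions:
        ra = calls_a.get(region.region_id)
        rb = calls_b.get(region.region_id)
        if ra is None or rb is None:
            continue
        pa = build_haplotype_pair(ra, th_dp=th_dp)
        pb = build_haplotype_pair(rb, th_dp=th_dp)
        if (
            pa is None
            or pb is None
            or not is_valid_pair(pa)
            or not is_valid_pair(pb)
        ):
            continue
        mode_a, mode_b = mhm(pa), mhm(pb)
        base = dict(
            region_id=region.region_id,
            chrom=region.chrom,
            start=region.start,
            end=region.end,
            mhm_a=mode_a,
            mhm_b=mode_b,
        )
        if mode_a == mode_b:
            records.append(
                DmrRecord(**base, mhd=None, p_value=None, is_dmr=False)
            )
            continue
        observed = _pair_mhd(pa, pb)
        assert observed is not None
        if observed <= mhd_min:
            records.append(
                DmrRecord(**base, mhd=observed, p_value=None, is_dmr=False)
            )
            continue
        p, _degenerate = region_p_value(
            ra, rb, observed, n_perm=n_perm, seed=rng, th_dp=th_dp
        )
        if p < alpha:
            dmr_type, subtype = classify_dmr(mode_a, mode_b)
            records.append(
                DmrRecord(
                    **base,
                    mhd=observed,
                    p_value=p,
                    is_dmr=True,
                    dmr_type=dmr_type,
                    subtype=subtype,
                )
            )
        else:
            records.append(
                DmrRecord(**base, mhd=observed, p_value=p, is_dmr=False)
            )
    return records


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional post-filter)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def write_dmr_table(records: Sequence[DmrRecord], path: str) -> None:
    """DMR results as BED-compatible TSV."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tregion_id\tmhm_group1\tmhm_group2\t"
            "mhd\tp_value\tis_dmr\ttype\tsubtype\n"
        )
        for r in records:
            mhd_s = "NA" if r.mhd is None else f"{r.mhd:.6g}"
            p_s = "NA" if r.p_value is None else f"{r.p_value:.6g}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.mhm_a}\t"
                f"{r.mhm_b}\t{mhd_s}\t{p_s}\t{int(r.is_dmr)}\t"
                f"{r.dmr_type if r.dmr_type is not None else 'NA'}\t"
                f"{r.subtype if r.subtype is not None else 'NA'}\n"
            )
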