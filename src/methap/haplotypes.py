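"""Paired methylation haplotypes, MH levels, modes and consistency metrics.

A region's two haplotypes are built in two steps: the *skeleton* links
the phases of neighbouring heterozygous sites into two anti-assigned
partial strings, and homozygous sites are then *padded* into both
strings. Sites that are filtered, ambiguous, or heterozygous but outside
the phase chain stay uncovered and are simply absent from the strings.

Each 0-1 string s has a methylation haplotype level
MH(s) = (number of 1s) / len(s), discretised into a label::

    L if MH <= 0.25,  N if MH <= 0.5,  M if MH <= 0.75,  H otherwise

and the pair of labels, higher-MH haplotype first, is the methylation
haplotype mode (MHM), e.g. HH, HL, LL. Pairs covering more than 3 CpG
sites are valid methylation haplotypes (VMHs); consistency metrics are
CpG-weighted fractions of VMHs whose mode is concordant (HH or LL; LL
only for hypomethylation consistency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from methap.methylation_calls import ReadCallSet
from methap.zygosity import (
    PhaseLink,
    ZygosityClass,
    ZygosityResult,
    resolve_region,
)

__all__ = [
    "HaplotypePair",
    "ConsistencyReport",
    "build_skeleton",
    "pad_homozygous",
    "build_haplotype_pair",
    "is_valid_pair",
    "mh_level",
    "label",
    "mhm",
    "consistency",
    "consistency_report",
]

MIN_VMH_COVERED = 4  # "covering more than 3 CpG sites"

LABEL_THRESHOLDS = ((0.25, "L"), (0.5, "N"), (0.75, "M"))


def mh_level(s: str) -> float:
    """Fraction of methylated (1) sites in a 0-1 haplotype string."""
    if not s:
        raise ValueError("MH level of an empty string is undefined")
    return s.count("1") / len(s)


def label(s: str) -> str:
    """Discretise a haplotype string's MH level into L/N/M/H."""
    mh = mh_level(s)
    for threshold, lab in LABEL_THRESHOLDS:
        if mh <= threshold:
            return lab
    return "H"


@dataclass(frozen=True)
class HaplotypePair:
    """The two reconstructed methylation haplotypes of one region.

    ``s1``/``s2`` run over ``covered_indices`` only; uncovered CpGs are
    excluded rather than encoded as a third symbol. Homolog naming is
    arbitrary (phasing cannot identify parental origin) but
    deterministic.
    """

    region_id: str
    covered_indices: tuple[int, ...]
    s1: str
    s2: str

    def __post_init__(self) -> None:
        if len(self.s1) != len(self.s2) or len(self.s1) != len(self.covered_indices):
            raise ValueError("haplotype strings must align with covered indices")

    @property
    def n_covered(self) -> int:
        return len(self.covered_indices)

    @property
    def mh1(self) -> float:
        return mh_level(self.s1)

    @property
    def mh2(self) -> float:
        return mh_level(self.s2)

    @property
    def labels(self) -> tuple[str, str]:
        return label(self.s1), label(self.s2)

    @property
    def hi_lo(self) -> tuple[float, float]:
        """MH of the higher- and lower-MH haplotype."""
        return (max(self.mh1, self.mh2), min(self.mh1, self.mh2))


def is_valid_pair(pair: HaplotypePair, min_covered: int = MIN_VMH_COVERED) -> bool:
    """Valid methylation haplotype: covers more than 3 CpG sites."""
    return pair.n_covered >= min_covered


def mhm(pair: HaplotypePair) -> str:
    """Methylation haplotype mode: the two labels, higher MH first."""
    if pair.mh1 >= pair.mh2:
        hi, lo = pair.s1, pair.s2
    else:
        hi, lo = pair.s2, pair.s1
    return label(hi) + label(lo)


def build_skeleton(
    zygosity: ZygosityResult,
) -> tuple[tuple[int, ...], str, str]:
    """Link heterozygous-site phases into two anti-assigned skeletons.

    Walks the heterozygous sites in genomic order, extending the chain
    while consecutive sites share a two-pattern phase link (patterns
    anti-correlated at both ends). On a break the longest prefix chain is
    kept and the remaining heterozygous sites stay uncovered. Haplotype 1
    takes the lexicographically smaller status at the first chain site.
    """
    het = zygosity.indices_of(ZygosityClass.HETEROZYGOUS)
    if not het:
        return (), "", ""
    link_map: dict[tuple[int, int], PhaseLink] = {
        (l.u, l.v): l for l in zygosity.links
    }
    chain = [het[0]]
    s1 = ["0"]
    s2 = ["1"]
    for u, v in zip(het, het[1:]):
        link = link_map.get((u, v))
        if link is None or len(link.patterns) != 2:
            break
        by_first = {p[0]: p[1] for p in link.patterns}
        if set(by_first) != {"0", "1"} or by_first["0"] == by_first["1"]:
            break  # not a phase-informative anti-correlated pair
        chain.append(v)
        s1.append(by_first[s1[-1]])
        s2.append(by_first[s2[-1]])
    return tuple(chain), "".join(s1), "".join(s2)


def pad_homozygous(
    region_id: str,
    skeleton_indices: Sequence[int],
    skeleton_s1: str,
    skeleton_s2: str,
    zygosity: ZygosityResult,
) -> HaplotypePair:
    """Pad homozygous sites into the skeletons to form the final pair.

    Each homozygous site contributes its status to both strings at its
    index; filtered/ambiguous sites (and heterozygous sites outside the
    chain) stay uncovered.
    """
    at: dict[int, tuple[str, str]] = {
        idx: (skeleton_s1[k], skeleton_s2[k])
        for k, idx in enumerate(skeleton_indices)
    }
    for idx, call in zygosity.calls.items():
        if call.zclass is ZygosityClass.HOMOZYGOUS:
            c = str(call.homozygous_status)
            at[idx] = (c, c)
    covered = tuple(sorted(at))
    s1 = "".join(at[i][0] for i in covered)
    s2 = "".join(at[i][1] for i in covered)
    return HaplotypePair(region_id=region_id, covered_indices=covered, s1=s1, s2=s2)


def build_haplotype_pair(
    reads: ReadCallSet,
    th_dp: int = 10,
    **zygosity_kwargs,
) -> HaplotypePair | None:
    """Resolve zygosity, build skeletons and pad for one region's reads.

    Returns None when no CpG site is covered at sufficient depth.
    """
    result = resolve_region(reads, th_dp=th_dp, **zygosity_kwargs)
    chain, s1, s2 = build_skeleton(result)
    pair = pad_homozygous(reads.region_id, chain, s1, s2, result)
    return pair if pair.n_covered > 0 else None


@dataclass(frozen=True)
class ConsistencyReport:
    """CpG-weighted MHM concordance between homologous chromosomes."""

    scope: str
    n_cpg_total: int
    n_cpg_meth_consistent: int
    n_cpg_hypo_consistent: int

    @property
    def methylation_consistency(self) -> float | None:
        if self.n_cpg_total == 0:
            return None
        return self.n_cpg_meth_consistent / self.n_cpg_total

    @property
    def hypomethylation_consistency(self) -> float | None:
        if self.n_cpg_total == 0:
            return None
        return self.n_cpg_hypo_consistent / self.n_cpg_total


def consistency(
    pairs: Iterable[HaplotypePair],
    mode_set: frozenset[str] | set[str] = frozenset({"HH", "LL"}),
    min_covered: int = MIN_VMH_COVERED,
) -> float | None:
    """CpG-weighted fraction of valid pairs whose MHM is in ``mode_set``.

    Returns None when no valid pair exists in scope.
    """
    num = den = 0
    for pair in pairs:
        if not is_valid_pair(pair, min_covered):
            continue
        den += pair.n_covered
        if mhm(pair) in mode_set:
            num += pair.n_covered
    return None if den == 0 else num / den


def consistency_report(
    pairs: Iterable[HaplotypePair],
    scope: str = "genome",
    min_covered: int = MIN_VMH_COVERED,
) -> ConsistencyReport:
    total = meth = hypo = 0
    for pair in pairs:
        if not is_valid_pair(pair, min_covered):
            continue
        total += pair.n_covered
        mode = mhm(pair)
        if mode in ("HH", "LL"):
            meth += pair.n_covered
        if mode == "LL":
            hypo += pair.n_covered
    return ConsistencyReport(
        scope=scope,
        n_cpg_total=total,
        n_cpg_meth_consistent=meth,
        n_cpg_hypo_consistent=hypo,
    )


def write_haplotype_table(
    pairs: Mapping[str, HaplotypePair | None], path: str
) -> None:
    """Haplotype table TSV: one row per region with a reconstructed pair."""
    with open(path, "w") as fh:
        fh.write("region_id\tcovered_cpg_count\ts1\ts2\tmh1\tmh2\tmhm\tvalid\n")
        for region_id in sorted(pairs):
            pair = pairs[region_id]
            if pair is None:
                continue
            fh.write(
                f"{pair.region_id}\t{pair.n_covered}\t{pair.s1}\t{pair.s2}\t"
                f"{pair.mh1:.6g}\t{pair.mh2:.6g}\t{mhm(pair)}\t"
                f"{int(is_valid_pair(pair))}\n"
            )
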