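"""Homozygous/heterozygous classification of CpG sites from read patterns.

"Zygosity" here is methylation zygosity, not genetic zygosity: a CpG is
heterozygous when its methylation status differs between the two
homologous chromosomes. Classification proceeds in two stages:

1. per-site screening on depth — sites below the depth threshold
   ``th_dp`` are filtered; a single-status site of sufficient depth is
   homozygous; a site showing both statuses, each at depth >= th_dp/2,
   is a candidate heterozygous site (CHS);
2. pattern-based resolution — the joint 00/01/10/11 statuses of
   neighbouring CHSs on co-covering reads identify one or two
   true-positive patterns via frequency-ratio rules (min count 2, single
   pattern if top/total > 0.6, two patterns if second/top >= 0.4), from
   which each CHS is reclassified as truly heterozygous or homozygous.
   Conflicts at a shared site are arbitrated by a confidence score: the
   total true-pattern frequency over the maximum depth among the three
   sites involved.

The resolved heterozygous sites carry pairwise phase links used to build
haplotype skeletons downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from methap.methylation_calls import ReadCallSet, SitePileup, pileup

__all__ = [
    "ZygosityClass",
    "ZygosityCall",
    "JointPatternCounts",
    "TruePatternSet",
    "PhaseLink",
    "ZygosityResult",
    "initial_classify",
    "joint_pattern_counts",
    "select_true_patterns",
    "reclassify_from_patterns",
    "confidence",
    "resolve_chain",
    "resolve_region",
]

PATTERNS = ("00", "01", "10", "11")

#: default depth threshold; the CHS rule then needs >= 5 reads per status
DEFAULT_TH_DP = 10
DEFAULT_MIN_PATTERN_FREQ = 2
DEFAULT_SINGLE_RATIO = 0.6
DEFAULT_SECOND_RATIO = 0.4


class ZygosityClass(Enum):
    HOMOZYGOUS = "homozygous"
    CANDIDATE_HET = "candidate_het"
    HETEROZYGOUS = "heterozygous"
    FILTERED = "filtered"
    AMBIGUOUS = "ambiguous"


@dataclass
class ZygosityCall:
    cpg_index: int
    zclass: ZygosityClass
    homozygous_status: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.zclass is ZygosityClass.HOMOZYGOUS and self.homozygous_status not in (0, 1):
            raise ValueError("homozygous call requires a 0/1 status")


@dataclass(frozen=True)
class JointPatternCounts:
    """Counts of the four joint status patterns at a CHS pair (u, v).

    Pattern strings are ordered: "01" means status 0 at u, 1 at v.
    """

    u: int
    v: int
    f: dict[str, int]

    def total(self) -> int:
        return sum(self.f.values())


@dataclass(frozen=True)
class TruePatternSet:
    """The one or two patterns retained as real at a CHS pair.

    Empty ``patterns`` marks the pair ambiguous. ``counts`` keeps the
    observed frequency of each retained pattern for confidence scoring.
    """

    u: int
    v: int
    patterns: tuple[str, ...]
    counts: dict[str, int] = field(default_factory=dict)

    def total_freq(self) -> int:
        return sum(self.counts.get(p, 0) for p in self.patterns)

    def restricted(self, first_statuses: set[int]) -> "TruePatternSet":
        """Subset of patterns whose status at u lies in ``first_statuses``."""
        kept = tuple(p for p in self.patterns if int(p[0]) in first_statuses)
        return TruePatternSet(u=self.u, v=self.v, patterns=kept, counts=self.counts)


@dataclass(frozen=True)
class PhaseLink:
    """Phase information between two neighbouring resolved CpG sites."""

    u: int
    v: int
    patterns: tuple[str, ...]


def initial_classify(site: SitePileup, th_dp: int = DEFAULT_TH_DP) -> ZygosityCall:
    """Depth-based screen of one CpG site.

    Sites below depth ``th_dp`` are filtered. Single-status sites are
    homozygous. Sites with both statuses each at depth >= th_dp/2 are
    CHSs. A two-status site whose minor status falls below th_dp/2 is
    called homozygous for the major status, treating the minor reads as
    sequencing/bisulfite-conversion noise; an exact tie below the
    threshold is filtered.
    """
    if th_dp < 2:
        raise ValueError("th_dp must be >= 2")
    if site.depth < th_dp:
        return ZygosityCall(site.cpg_index, ZygosityClass.FILTERED, note="low depth")
    half = th_dp / 2
    if site.n_meth == 0 or site.n_unmeth == 0:
        status = 1 if site.n_meth > 0 else 0
        return ZygosityCall(site.cpg_index, ZygosityClass.HOMOZYGOUS, status)
    if site.n_meth >= half and site.n_unmeth >= half:
        return ZygosityCall(site.cpg_index, ZygosityClass.CANDIDATE_HET)
    if site.n_meth == site.n_unmeth:
        return ZygosityCall(site.cpg_index, ZygosityClass.FILTERED, note="tied below threshold")
    major = 1 if site.n_meth > site.n_unmeth else 0
    return ZygosityCall(
        site.cpg_index, ZygosityClass.HOMOZYGOUS, major, note="minor status as noise"
    )


def joint_pattern_counts(reads: ReadCallSet, u: int, v: int) -> JointPatternCounts:
    """Count joint statuses at (u, v) over reads covering both sites."""
    f = {p: 0 for p in PATTERNS}
    for _read_id, calls in reads.reads:
        if u in calls and v in calls:
            f[f"{calls[u]}{calls[v]}"] += 1
    return JointPatternCounts(u=u, v=v, f=f)


def select_true_patterns(
    counts: JointPatternCounts,
    min_freq: int = DEFAULT_MIN_PATTERN_FREQ,
    single_ratio: float = DEFAULT_SINGLE_RATIO,
    second_ratio: float = DEFAULT_SECOND_RATIO,
) -> TruePatternSet:
    """Frequency-ratio selection of one or two true-positive patterns.

    After dropping patterns seen fewer than ``min_freq`` times: a unique
    top pattern whose share of the total exceeds ``single_ratio`` is the
    single true pattern; otherwise the top two are both true when the
    second-to-top ratio is at least ``second_ratio``. Ties that leave no
    identifiable top one or two patterns, or an empty survivor set, make
    the pair ambiguous.
    """
    surviving = {p: c for p, c in counts.f.items() if c >= min_freq}
    if not surviving:
        return TruePatternSet(counts.u, counts.v, ())
    total = sum(surviving.values())
    ranked = sorted(surviving.items(), key=lambda item: (-item[1], item[0]))
    top_count = ranked[0][1]
    top_ties = [p for p, c in ranked if c == top_count]
    if len(top_ties) == 1 and top_count / total > single_ratio:
        return TruePatternSet(counts.u, counts.v, (ranked[0][0],), dict(surviving))
    if len(top_ties) > 2:
        return TruePatternSet(counts.u, counts.v, ())
    if len(top_ties) == 2:
        # the two tied maxima are the top two iff no third equals them
        pair = tuple(sorted(top_ties))
        return TruePatternSet(counts.u, counts.v, pair, dict(surviving))
    if len(ranked) >= 2:
        second_count = ranked[1][1]
        second_ties = [p for p, c in ranked if c == second_count]
        if len(second_ties) > 1:
            return TruePatternSet(counts.u, counts.v, ())
        if second_count / top_count >= second_ratio:
            pair = (ranked[0][0], ranked[1][0])
            return TruePatternSet(counts.u, counts.v, pair, dict(surviving))
    return TruePatternSet(counts.u, counts.v, ())


def reclassify_from_patterns(tp: TruePatternSet) -> tuple[ZygosityCall, ZygosityCall]:
    """Derive site classes at (u, v) from the true-positive patterns.

    A site is heterozygous iff both statuses appear at its position
    across the patterns; otherwise homozygous for the single status.
    An empty pattern set leaves both sites ambiguous.
    """
    if not tp.patterns:
        return (
            ZygosityCall(tp.u, ZygosityClass.AMBIGUOUS),
            ZygosityCall(tp.v, ZygosityClass.AMBIGUOUS),
        )
    calls = []
    for pos, idx in ((0, tp.u), (1, tp.v)):
        statuses = {int(p[pos]) for p in tp.patterns}
        if statuses == {0, 1}:
            calls.append(ZygosityCall(idx, ZygosityClass.HETEROZYGOUS))
        else:
            calls.append(ZygosityCall(idx, ZygosityClass.HOMOZYGOUS, statuses.pop()))
    return calls[0], calls[1]


def confidence(tp: TruePatternSet, *depths: int) -> float:
    """Confidence of a CHS pair: total true-pattern frequency over the
    maximum depth among the involved CpG sites (two at a region boundary,
    three elsewhere)."""
    max_depth = max(depths) if depths else 0
    if max_depth <= 0:
        warnings.warn("confidence undefined at zero depth; returning 0")
        return 0.0
    return tp.total_freq() / max_depth


@dataclass
class ZygosityResult:
    """Final per-site classes and the phase links between resolved sites."""

    calls: dict[int, ZygosityCall]
    links: list[PhaseLink]

    def indices_of(self, zclass: ZygosityClass) -> list[int]:
        return sorted(i for i, c in self.calls.items() if c.zclass is zclass)


def _classes_from_patterns(tp: TruePatternSet) -> tuple[ZygosityCall, ZygosityCall]:
    return reclassify_from_patterns(tp)


def resolve_chain(
    chs_indices: Sequence[int],
    reads: ReadCallSet,
    pileups: Sequence[SitePileup],
    min_freq: int = DEFAULT_MIN_PATTERN_FREQ,
    single_ratio: float = DEFAULT_SINGLE_RATIO,
    second_ratio: float = DEFAULT_SECOND_RATIO,
) -> tuple[dict[int, ZygosityCall], list[PhaseLink]]:
    """Left-to-right sweep over neighbouring CHS pairs.

    For successive pairs (u, v) and (v, w) sharing site v, the pair with
    the higher confidence decides v: if the earlier pair wins, v keeps
    its class and w is derived from the (v, w) patterns restricted to
    those compatible with v; if the later pair wins, v is revised from
    the (v, w) patterns. A single CHS with no neighbour stays ambiguous.
    Returns final calls for every CHS plus the phase links actually used.
    """
    depth = {p.cpg_index: p.depth for p in pileups}
    calls: dict[int, ZygosityCall] = {
        i: ZygosityCall(i, ZygosityClass.AMBIGUOUS) for i in chs_indices
    }
    links: dict[tuple[int, int], PhaseLink] = {}
    if len(chs_indices) < 2:
        return calls, []

    def select(u: int, v: int) -> TruePatternSet:
        return select_true_patterns(
            joint_pattern_counts(reads, u, v), min_freq, single_ratio, second_ratio
        )

    prev_tp: TruePatternSet | None = None  # TP set governing the previous pair
    prev_u: int | None = None
    for u, v in zip(chs_indices, chs_indices[1:]):
        tp = select(u, v)
        fresh = (
            prev_tp is None
            or calls[u].zclass is ZygosityClass.AMBIGUOUS
        )
        if fresh:
            cu, cv = _classes_from_patterns(tp)
            calls[u], calls[v] = cu, cv
            if tp.patterns:
                links[(u, v)] = PhaseLink(u, v, tp.patterns)
            prev_tp, prev_u = (tp, u) if tp.patterns else (None, None)
            continue
        if not tp.patterns:
            # no usable evidence for the new pair; v stays as classified
            # later (ambiguous) and the chain restarts after it
            prev_tp, prev_u = None, None
            continue
        # conflict arbitration over shared site u (the "v" of the triple)
        assert prev_u is not None and prev_tp is not None
        d_three = (depth.get(prev_u, 0), depth.get(u, 0), depth.get(v, 0))
        conf_prev = confidence(prev_tp, *d_three)
        conf_cur = confidence(tp, *d_three)
        if conf_prev >= conf_cur:
            if calls[u].zclass is ZygosityClass.HETEROZYGOUS:
                allowed = {0, 1}
            else:
                allowed = {calls[u].homozygous_status}
            tp_used = tp.restricted(allowed)
            if not tp_used.patterns:
                calls[v] = ZygosityCall(v, ZygosityClass.AMBIGUOUS)
                prev_tp, prev_u = None, None
                continue
            _, cv = _classes_from_patterns(tp_used)
            calls[v] = cv
            links[(u, v)] = PhaseLink(u, v, tp_used.patterns)
            prev_tp, prev_u = tp_used, u
        else:
            cu, cv = _classes_from_patterns(tp)
            calls[u], calls[v] = cu, cv
            links[(u, v)] = PhaseLink(u, v, tp.patterns)
            # the earlier link through u may now contradict u's revision
            stale = links.get((prev_u, u))
            if stale is not None and not _link_consistent(stale, calls[prev_u], calls[u]):
                del links[(prev_u, u)]
            prev_tp, prev_u = tp, u
    return calls, [links[k] for k in sorted(links)]


def _link_consistent(
    link: PhaseLink, cu: ZygosityCall, cv: ZygosityCall
) -> bool:
    """A link is usable only if its patterns imply its endpoints' classes."""
    for pos, call in ((0, cu), (1, cv)):
        statuses = {int(p[pos]) for p in link.patterns}
        if call.zclass is ZygosityClass.HETEROZYGOUS:
            if statuses != {0, 1}:
                return False
        elif call.zclass is ZygosityClass.HOMOZYGOUS:
            if statuses != {call.homozygous_status}:
                return False
        else:
            return False
    return True


def resolve_region(
    reads: ReadCallSet,
    th_dp: int = DEFAULT_TH_DP,
    min_freq: int = DEFAULT_MIN_PATTERN_FREQ,
    single_ratio: float = DEFAULT_SINGLE_RATIO,
    second_ratio: float = DEFAULT_SECOND_RATIO,
) -> ZygosityResult:
    """Full zygosity resolution for one region's reads.

    Runs the depth screen on every CpG, then the pattern-based chain
    sweep over the candidate heterozygous sites. Every CpG index of the
    region receives exactly one final class.
    """
    piles = pileup(reads)
    calls = {p.cpg_index: initial_classify(p, th_dp) for p in piles}
    chs = sorted(i for i, c in calls.items() if c.zclass is ZygosityClass.CANDIDATE_HET)
    resolved, links = resolve_chain(
        chs, reads, piles, min_freq, single_ratio, second_ratio
    )
    calls.update(resolved)
    return ZygosityResult(calls=calls, links=links)
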