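"""Sample-independent candidate regions from CpG coordinates and CpG islands.

Methylation haplotypes are only reconstructable where CpG sites are dense
enough for single reads to bridge neighbouring sites, so all downstream
analysis is restricted to candidate regions defined from the genome alone:

* CpG islands are divided into consecutive blocks of at least ``min_cpg``
  (default 7) CpG sites each;
* outside islands, a distance-based clustering groups CpGs whose
  neighbouring sites are at most ``max_gap`` (default 20) bp apart, again
  keeping only clusters of at least ``min_cpg`` sites.

Coordinates are 0-based half-open throughout (BED convention); a CpG site
is identified by the position of the C on the forward strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "CpGCatalog",
    "CandidateRegion",
    "extract_cpg_catalog",
    "split_island",
    "cluster_dense_cpgs",
    "generate_candidate_regions",
    "read_islands_bed",
    "write_regions_bed",
    "read_regions_bed",
]

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")

#: minimum CpG sites per candidate region
MIN_CPG = 7
#: maximum gap (bp) between neighbouring CpGs in a non-island cluster
MAX_GAP = 20


@dataclass(frozen=True)
class CpGCatalog:
    """All forward-strand CpG dinucleotide coordinates of one chromosome."""

    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("CpG positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class CandidateRegion:
    """A genomic interval spanning an ordered run of CpG sites.

    ``start``/``end`` span the first to last contained CpG (the end
    includes the G of the final dinucleotide). ``source`` records whether
    the region came from island splitting or from distance clustering.
    """

    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]
    source: str  # "island" | "cluster"
    region_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.cpg_positions) < MIN_CPG:
            raise ValueError("candidate region needs >= 7 CpG sites")
        if not all(self.start <= p < self.end for p in self.cpg_positions):
            raise ValueError("CpG positions outside region interval")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    def cpg_index(self, position: int) -> int | None:
        """Region-local index of the CpG at ``position``, or None."""
        try:
            return self.cpg_positions.index(position)
        except ValueError:
            return None


def extract_cpg_catalog(sequences: dict[str, str]) -> dict[str, CpGCatalog]:
    """Scan per-chromosome sequences for forward-strand CG dinucleotides.

    Case-insensitive; dinucleotides containing N are excluded. Characters
    outside {A,C,G,T,N} are rejected.
    """
    catalogs: dict[str, CpGCatalog] = {}
    for chrom, seq in sequences.items():
        if not _VALID_SEQ.match(seq):
            raise ValueError(f"non-nucleotide characters in sequence for {chrom}")
        upper = seq.upper()
        positions = tuple(m.start() for m in re.finditer("(?=CG)", upper))
        catalogs[chrom] = CpGCatalog(chrom=chrom, positions=positions)
    return catalogs


def _balanced_blocks(positions: Sequence[int], min_cpg: int) -> list[tuple[int, ...]]:
    """Partition an ordered CpG list into floor(n/min_cpg) consecutive
    near-equal blocks (sizes differ by <= 1, each >= min_cpg)."""
    n = len(positions)
    k = n // min_cpg
    if k == 0:
        return []
    base, extra = divmod(n, k)
    blocks: list[tuple[int, ...]] = []
    i = 0
    for b in range(k):
        size = base + (1 if b < extra else 0)
        blocks.append(tuple(positions[i : i + size]))
        i += size
    return blocks


def _region_from_block(
    chrom: str, block: tuple[int, ...], source: str
) -> CandidateRegion:
    return CandidateRegion(
        chrom=chrom,
        start=block[0],
        end=block[-1] + 2,
        cpg_positions=block,
        source=source,
    )


def split_island(
    island: tuple[int, int], catalog: CpGCatalog, min_cpg: int = MIN_CPG
) -> list[CandidateRegion]:
    """Divide one CpG island into candidate regions of >= ``min_cpg`` CpGs.

    The island's contained CpGs are partitioned into floor(n/min_cpg)
    consecutive balanced blocks; islands with fewer than ``min_cpg``
    contained CpGs yield nothing.
    """
    start, end = island
    inside = [p for p in catalog.positions if start <= p < end]
    return [
        _region_from_block(catalog.chrom, block, "island")
        for block in _balanced_blocks(inside, min_cpg)
    ]


def _in_any_interval(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _interval_between(
    left: int, right: int, intervals: Sequence[tuple[int, int]]
) -> bool:
    """True if any interval overlaps the open span between two CpG sites."""
    return any(s < right and e > left + 2 for s, e in intervals)


def cluster_dense_cpgs(
    catalog: CpGCatalog,
    island_intervals: Sequence[tuple[int, int]],
    max_gap: int = MAX_GAP,
    min_cpg: int = MIN_CPG,
) -> list[CandidateRegion]:
    """Cluster non-island CpGs whose neighbours are <= ``max_gap`` bp apart.

    Maximal runs with every consecutive coordinate difference <= ``max_gap``
    become regions when they hold >= ``min_cpg`` CpGs; runs of more than
    2 * ``min_cpg`` sites are split into balanced blocks like islands.
    Runs never extend across an island interval, which keeps cluster
    regions disjoint from island-derived ones.
    """
    outside = [p for p in catalog.positions if not _in_any_interval(p, island_intervals)]
    regions: list[CandidateRegion] = []
    run: list[int] = []

    def _flush() -> None:
        if len(run) >= min_cpg:
            if len(run) > 2 * min_cpg:
                blocks = _balanced_blocks(run, min_cpg)
            else:
                blocks = [tuple(run)]
            for block in blocks:
                regions.append(_region_from_block(catalog.chrom, block, "cluster"))
        run.clear()

    for pos in outside:
        if run and (
            pos - run[-1] > max_gap
            or _interval_between(run[-1], pos, island_intervals)
        ):
            _flush()
        run.append(pos)
    _flush()
    return regions


def generate_candidate_regions(
    catalogs: dict[str, CpGCatalog],
    islands: dict[str, list[tuple[int, int]]],
    max_gap: int = MAX_GAP,
    min_cpg: int = MIN_CPG,
) -> list[CandidateRegion]:
    """Island splitting plus non-island clustering, sorted and non-overlapping.

    Returns regions sorted by (chrom, start) with sequential region ids.
    Raises if an island-derived and a cluster-derived region overlap,
    which would indicate a masking defect.
    """
    regions: list[CandidateRegion] = []
    for chrom in sorted(catalogs):
        catalog = catalogs[chrom]
        chrom_islands = sorted(islands.get(chrom, []))
        chrom_regions: list[CandidateRegion] = []
        for island in chrom_islands:
            chrom_regions.extend(split_island(island, catalog, min_cpg))
        chrom_regions.extend(
            cluster_dense_cpgs(catalog, chrom_islands, max_gap, min_cpg)
        )
        chrom_regions.sort(key=lambda r: r.start)
        for a, b in zip(chrom_regions, chrom_regions[1:]):
            if b.start < a.end:
                raise AssertionError(
                    f"overlapping candidate regions on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        regions.extend(chrom_regions)
    return [
        CandidateRegion(
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            cpg_positions=r.cpg_positions,
            source=r.source,
            region_id=f"region_{i:06d}",
        )
        for i, r in enumerate(regions)
    ]


# ---------------------------------------------------------------------------
# plain-text I/O


def read_islands_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read CpG island intervals from a >= 3 column BED file."""
    islands: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            islands.setdefault(chrom, []).append((int(start), int(end)))
    return islands


def write_regions_bed(regions: Iterable[CandidateRegion], path: str) -> None:
    """Write regions as BED6-compatible TSV with CpG positions in column 7."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tregion_id\tcpg_count\tsource\tcpg_positions\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.n_cpg}\t"
                f"{r.source}\t{','.join(map(str, r.cpg_positions))}\n"
            )


def read_regions_bed(path: str) -> list[CandidateRegion]:
    regions: list[CandidateRegion] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, rid, _count, source, cpgs = line.rstrip("\n").split("\t")
            regions.append(
                CandidateRegion(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    cpg_positions=tuple(int(p) for p in cpgs.split(",")),
                    source=source,
                    region_id=rid,
                )
            )
    return regions


def iter_fasta(path: str) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTA file via pyfaidx."""
    from pyfaidx import Fasta

    with Fasta(path, as_raw=True) as fa:
        for name in fa.keys():
            yield name, str(fa[name][:])
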