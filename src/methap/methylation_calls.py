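"""Per-read CpG methylation calls inside candidate regions.

Reads arrive either as Bismark-style alignments (SAM/BAM with an ``XM``
per-base methylation string: ``Z`` = methylated CpG, ``z`` = unmethylated
CpG, other codes ignored) or as a simple TSV dialect with columns
``read_id, chrom, cpg_position, status``.

Both strands report to a single CpG unit, keyed by the forward-strand C
coordinate: a bottom-strand call at coordinate p+1 is folded onto the
forward CpG at p. Overlapping mates are deduplicated with a
first-mate-wins rule so a fragment never contributes depth twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from methap.genome_regions import CandidateRegion

__all__ = [
    "ReadCallSet",
    "SitePileup",
    "pileup",
    "parse_alignment_calls",
    "read_calls_tsv",
    "write_calls_tsv",
]


@dataclass
class ReadCallSet:
    """Per-read methylation statuses at region-local CpG indices."""

    region_id: str
    n_cpg: int
    reads: list[tuple[str, dict[int, int]]] = field(default_factory=list)

    def add_read(self, read_id: str, calls: Mapping[int, int]) -> None:
        for idx, status in calls.items():
            if not 0 <= idx < self.n_cpg:
                raise ValueError(f"CpG index {idx} outside region of {self.n_cpg} sites")
            if status not in (0, 1):
                raise ValueError(f"status must be 0/1, got {status!r}")
        self.reads.append((read_id, dict(calls)))

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class SitePileup:
    """Status counts at one CpG site."""

    cpg_index: int
    n_meth: int
    n_unmeth: int

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    def count(self, status: int) -> int:
        return self.n_meth if status == 1 else self.n_unmeth


def pileup(read_calls: ReadCallSet) -> list[SitePileup]:
    """Column sums of the read-by-CpG call matrix; unseen sites get depth 0."""
    n_meth = [0] * read_calls.n_cpg
    n_unmeth = [0] * read_calls.n_cpg
    for _read_id, calls in read_calls.reads:
        for idx, status in calls.items():
            if status == 1:
                n_meth[idx] += 1
            else:
                n_unmeth[idx] += 1
    return [
        SitePileup(cpg_index=i, n_meth=m, n_unmeth=u)
        for i, (m, u) in enumerate(zip(n_meth, n_unmeth))
    ]


@dataclass
class ParseStats:
    """Counters emitted by the alignment parser."""

    n_records: int = 0
    n_used: int = 0
    n_skipped_flag: int = 0
    n_missing_tag: int = 0
    n_mate_conflicts: int = 0


def parse_alignment_calls(
    alignment_path: str,
    regions: Sequence[CandidateRegion],
    min_mapq: int = 0,
) -> tuple[dict[str, ReadCallSet], ParseStats]:
    """Extract CpG-context calls from a Bismark-style SAM/BAM per region.

    ``Z``/``z`` codes in the XM tag are mapped through the CIGAR to
    reference coordinates and then to region CpG indices; reverse-strand
    CpG calls (coordinate p+1) fold onto the forward unit at p. Unmapped,
    secondary, supplementary and duplicate-flagged records are skipped, as
    are records below ``min_mapq`` or lacking an XM tag. Overlapping
    mates: the first-encountered mate's call wins and conflicts are
    counted.
    """
    import pysam

    stats = ParseStats()
    result: dict[str, ReadCallSet] = {
        r.region_id: ReadCallSet(region_id=r.region_id, n_cpg=r.n_cpg)
        for r in regions
    }
    mode = "rb" if alignment_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(alignment_path, mode, check_sq=False) as af:
        has_index = af.has_index()
        if not has_index:
            # unindexed streams can only be read once; keep them in memory
            all_records = list(af.fetch(until_eof=True))
        for region in regions:
            pos_to_idx = {p: i for i, p in enumerate(region.cpg_positions)}
            # allow bottom-strand coordinate p+1 to report to the unit at p
            rev_to_idx = {p + 1: i for i, p in enumerate(region.cpg_positions)}
            if has_index:
                records = af.fetch(region.chrom, region.start, region.end)
            else:
                records = (
                    rec
                    for rec in all_records
                    if rec.reference_name == region.chrom
                    and rec.reference_start is not None
                    and rec.reference_start < region.end
                    and (rec.reference_end or 0) > region.start
                )
            fragment_calls: dict[str, dict[int, int]] = {}
            for rec in records:
                stats.n_records += 1
                if (
                    rec.is_unmapped
                    or rec.is_secondary
                    or rec.is_supplementary
                    or rec.is_duplicate
                    or rec.mapping_quality < min_mapq
                ):
                    stats.n_skipped_flag += 1
                    continue
                if not rec.has_tag("XM"):
                    stats.n_missing_tag += 1
                    continue
                xm = rec.get_tag("XM")
                calls = fragment_calls.setdefault(rec.query_name, {})
                for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                    code = xm[qpos]
                    if code not in ("Z", "z"):
                        continue
                    idx = pos_to_idx.get(rpos)
                    if idx is None:
                        idx = rev_to_idx.get(rpos)
                    if idx is None:
                        continue
                    status = 1 if code == "Z" else 0
                    if idx in calls:
                        if calls[idx] != status:
                            stats.n_mate_conflicts += 1
                        continue  # first mate wins
                    calls[idx] = status
                stats.n_used += 1
            for read_id in sorted(fragment_calls):
                calls = fragment_calls[read_id]
                if calls:
                    result[region.region_id].add_read(read_id, calls)
    return result, stats


# ---------------------------------------------------------------------------
# TSV call dialect: read_id, chrom, cpg_position, status (header required)


def write_calls_tsv(
    call_sets: Mapping[str, ReadCallSet],
    regions: Sequence[CandidateRegion],
    path: str,
) -> None:
    by_id = {r.region_id: r for r in regions}
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tcpg_position\tstatus\n")
        for region_id in sorted(call_sets):
            region = by_id[region_id]
            for read_id, calls in call_sets[region_id].reads:
                for idx in sorted(calls):
                    fh.write(
                        f"{read_id}\t{region.chrom}\t"
                        f"{region.cpg_positions[idx]}\t{calls[idx]}\n"
                    )


def read_calls_tsv(
    path: str, regions: Sequence[CandidateRegion]
) -> dict[str, ReadCallSet]:
    """Load the TSV call dialect and index calls into region CpG indices.

    Calls at positions outside every region are ignored; a read spanning
    two regions contributes to both independently.
    """
    pos_index: dict[tuple[str, int], tuple[str, int]] = {}
    result: dict[str, ReadCallSet] = {}
    for r in regions:
        result[r.region_id] = ReadCallSet(region_id=r.region_id, n_cpg=r.n_cpg)
        for i, p in enumerate(r.cpg_positions):
            pos_index[(r.chrom, p)] = (r.region_id, i)

    per_read: dict[tuple[str, str], dict[int, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["read_id", "chrom", "cpg_position", "status"]:
            raise ValueError("calls TSV must start with the documented header")
        for line in fh:
            if not line.strip():
                continue
            read_id, chrom, pos, status = line.rstrip("\n").split("\t")[:4]
            hit = pos_index.get((chrom, int(pos)))
            if hit is None:
                continue
            region_id, idx = hit
            per_read.setdefault((region_id, read_id), {})[idx] = int(status)
    for (region_id, read_id), calls in per_read.items():
        result[region_id].add_read(read_id, calls)
    for rcs in result.values():
        rcs.reads.sort(key=lambda item: item[0])
    return result
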