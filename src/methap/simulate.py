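"""Synthetic paired-homolog bisulfite data with known truth.

The simulator emulates the read-level evidence the pipeline consumes: a
diploid locus carries two methylation template strings (one per
homologous chromosome) over a region's CpG sites; reads sample one
homolog uniformly, cover a contiguous window of CpGs, and report each
site's status with an independent per-call flip probability ``error_rate``.

Scenario kinds mirror biological situations with known expected outcomes:

* ``consistent`` — both homologs identical and fully hypo- or
  hypermethylated per region (expected consistency 1 at zero error),
  like autosomal CpG islands or the male X;
* ``x_inactivation`` — one homolog fully methylated, the other fully
  unmethylated (expected consistency 0), like the female inactive X;
* ``differentiation_shift`` — two samples where the second is
  hypomethylated in a declared extra fraction of regions, emulating
  methylation loss with differentiation;
* ``cancer_like`` — two samples where a fraction of LL regions become
  HH (and a smaller fraction the reverse), emulating tumour
  hypermethylation of CpG islands;
* ``dmr_panel`` — two samples, a declared fraction of regions planted
  as complete LL-vs-HH differences (MHD 1.0), the rest identical; the
  truth table lists every planted DMR.

Reads are simulated at the CpG-call level; an optional SAM rendering
writes Bismark-style alignments (XM tag) against a generated reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from methap.genome_regions import CandidateRegion
from methap.methylation_calls import ReadCallSet

__all__ = [
    "SimScenario",
    "RegionTruth",
    "synthetic_regions",
    "make_scenario",
    "emit_reads",
    "reference_sequence",
    "write_sam",
    "write_truth_tsv",
]

SIM_CHROM = "chrSim"

#: defaults chosen to resemble WGBS candidate regions: ~10 CpGs per
#: region spaced 8 bp (region span ~74 bp), 30x depth per homolog,
#: 1% per-call error. A 100-150 bp read covers such a region entirely,
#: so the default read span equals the region's CpG count.
DEFAULT_N_REGIONS = 200
DEFAULT_CPG_PER_REGION = 10
DEFAULT_DEPTH = 30
DEFAULT_ERROR_RATE = 0.01
DEFAULT_READ_SPAN = 10
CPG_SPACING = 8
REGION_GAP = 200


@dataclass(frozen=True)
class RegionTruth:
    """Planted templates and modes for one region."""

    region_id: str
    templates: dict[str, tuple[str, str]]  # sample_id -> (t1, t2)
    planted_mhm: dict[str, str]  # sample_id -> MHM
    is_planted_dmr: bool


@dataclass
class SimScenario:
    """A fully specified simulation: regions, per-sample templates, rates."""

    kind: str
    regions: list[CandidateRegion]
    sample_ids: list[str]
    templates: dict[str, dict[str, tuple[str, str]]]  # sample -> region -> (t1,t2)
    depth: int
    error_rate: float
    read_span: int
    seed: int
    truth: list[RegionTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


def synthetic_regions(
    n_regions: int = DEFAULT_N_REGIONS,
    cpg_per_region: int = DEFAULT_CPG_PER_REGION,
) -> list[CandidateRegion]:
    """Evenly laid-out candidate regions on a synthetic chromosome."""
    regions = []
    cursor = 100
    for i in range(n_regions):
        positions = tuple(cursor + k * CPG_SPACING for k in range(cpg_per_region))
        regions.append(
            CandidateRegion(
                chrom=SIM_CHROM,
                start=positions[0],
                end=positions[-1] + 2,
                cpg_positions=positions,
                source="cluster",
                region_id=f"sim_{i:05d}",
            )
        )
        cursor = positions[-1] + 2 + REGION_GAP
    return regions


def _mode_of(t1: str, t2: str) -> str:
    from methap.haplotypes import label, mh_level

    if mh_level(t1) >= mh_level(t2):
        return label(t1) + label(t2)
    return label(t2) + label(t1)


def make_scenario(
    kind: str,
    n_regions: int = DEFAULT_N_REGIONS,
    cpg_per_region: int = DEFAULT_CPG_PER_REGION,
    depth: int = DEFAULT_DEPTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    read_span: int = DEFAULT_READ_SPAN,
    dmr_fraction: float = 0.2,
    shift_fraction: float = 0.2,
    seed: int = 0,
) -> SimScenario:
    """Build a scenario of the given kind with planted truth.

    ``dmr_fraction`` applies to ``dmr_panel`` (fraction of regions planted
    as complete LL-vs-HH DMRs); ``shift_fraction`` applies to
    ``differentiation_shift``/``cancer_like`` (fraction of regions whose
    mode changes between the two samples).
    """
    rng = np.random.default_rng(seed)
    regions = synthetic_regions(n_regions, cpg_per_region)
    n = cpg_per_region
    all0, all1 = "0" * n, "1" * n
    samples: list[str]
    templates: dict[str, dict[str, tuple[str, str]]]
    truth: list[RegionTruth] = []

    if kind == "consistent":
        samples = ["sample1"]
        templates = {"sample1": {}}
        for r in regions:
            t = all1 if rng.random() < 0.5 else all0
            templates["sample1"][r.region_id] = (t, t)
    elif kind == "x_inactivation":
        samples = ["sample1"]
        templates = {"sample1": {r.region_id: (all0, all1) for r in regions}}
    elif kind == "differentiation_shift":
        samples = ["stem", "derived"]
        templates = {"stem": {}, "derived": {}}
        for r in regions:
            hypo_in_stem = rng.random() < 0.5
            t_stem = all0 if hypo_in_stem else all1
            templates["stem"][r.region_id] = (t_stem, t_stem)
            shifts = (not hypo_in_stem) and rng.random() < shift_fraction
            t_drv = all0 if (hypo_in_stem or shifts) else all1
            templates["derived"][r.region_id] = (t_drv, t_drv)
    elif kind == "cancer_like":
        samples = ["normal", "tumour"]
        templates = {"normal": {}, "tumour": {}}
        for r in regions:
            hypo_in_normal = rng.random() < 0.7
            t_norm = all0 if hypo_in_normal else all1
            templates["normal"][r.region_id] = (t_norm, t_norm)
            flip_p = shift_fraction if hypo_in_normal else shift_fraction / 5
            t_tum = (all1 if hypo_in_normal else all0) if rng.random() < flip_p else t_norm
            templates["tumour"][r.region_id] = (t_tum, t_tum)
    elif kind == "dmr_panel":
        samples = ["group1", "group2"]
        templates = {"group1": {}, "group2": {}}
        n_dmr = round(dmr_fraction * n_regions)
        dmr_ids = set(
            rng.choice(len(regions), size=n_dmr, replace=False).tolist()
        )
        for i, r in enumerate(regions):
            if i in dmr_ids:
                templates["group1"][r.region_id] = (all0, all0)
                templates["group2"][r.region_id] = (all1, all1)
            else:
                t = all1 if rng.random() < 0.5 else all0
                templates["group1"][r.region_id] = (t, t)
                templates["group2"][r.region_id] = (t, t)
    else:
        raise ValueError(f"unknown scenario kind: {kind!r}")

    for r in regions:
        per_sample = {s: templates[s][r.region_id] for s in samples}
        modes = {s: _mode_of(*per_sample[s]) for s in samples}
        truth.append(
            RegionTruth(
                region_id=r.region_id,
                templates=per_sample,
                planted_mhm=modes,
                is_planted_dmr=len(set(modes.values())) > 1,
            )
        )
    return SimScenario(
        kind=kind,
        regions=regions,
        sample_ids=samples,
        templates=templates,
        depth=depth,
        error_rate=error_rate,
        read_span=read_span,
        seed=seed,
        truth=truth,
    )


def emit_reads(scenario: SimScenario) -> dict[str, dict[str, ReadCallSet]]:
    """Draw reads for every sample and region of a scenario.

    Exactly ``depth`` reads are drawn from each homolog (the two
    homologs of a diploid cell are sequenced at the same expected
    coverage, and depth is specified per homolog). Each read covers a
    contiguous window of ``read_span`` CpGs at a uniform start and flips
    each call independently with probability ``error_rate``.
    Deterministic for a fixed scenario seed.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    out: dict[str, dict[str, ReadCallSet]] = {}
    for sample in scenario.sample_ids:
        out[sample] = {}
        for region in scenario.regions:
            t = scenario.templates[sample][region.region_id]
            n_cpg = region.n_cpg
            if scenario.read_span > n_cpg:
                warnings.warn(
                    f"read span {scenario.read_span} exceeds region CpG count "
                    f"{n_cpg}; clamping"
                )
            span = min(scenario.read_span, n_cpg)
            n_reads = 2 * scenario.depth
            rcs = ReadCallSet(region_id=region.region_id, n_cpg=n_cpg)
            homologs = rng.permutation(
                np.repeat(np.arange(2), scenario.depth)
            )
            starts = rng.integers(0, n_cpg - span + 1, size=n_reads)
            flips = rng.random(size=(n_reads, span)) < scenario.error_rate
            for k in range(n_reads):
                template = t[homologs[k]]
                start = int(starts[k])
                calls = {}
                for j in range(span):
                    status = int(template[start + j])
                    if flips[k, j]:
                        status = 1 - status
                    calls[start + j] = status
                rcs.add_read(f"{sample}_{region.region_id}_r{k:04d}", calls)
            out[sample][region.region_id] = rcs
    return out


# ---------------------------------------------------------------------------
# reference + SAM rendering (Bismark-style XM tags)


def reference_sequence(regions: Sequence[CandidateRegion]) -> str:
    """Synthetic chromosome: CG at every catalogued position, A elsewhere."""
    length = regions[-1].end + REGION_GAP
    seq = np.full(length, ord("A"), dtype=np.uint8)
    for r in regions:
        for p in r.cpg_positions:
            seq[p] = ord("C")
            seq[p + 1] = ord("G")
    return seq.tobytes().decode("ascii")


def write_sam(
    scenario: SimScenario,
    sample: str,
    read_calls: dict[str, ReadCallSet],
    path: str,
) -> None:
    """Render one sample's reads as a Bismark-style SAM file.

    Reads are written as forward-strand single-end alignments over the
    synthetic reference; methylated CpGs keep C (XM code Z), unmethylated
    CpGs are bisulfite-converted to T (XM code z).
    """
    ref_len = scenario.regions[-1].end + REGION_GAP
    by_id = {r.region_id: r for r in scenario.regions}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{SIM_CHROM}\tLN:{ref_len}\n")
        rows = []
        for region_id in sorted(read_calls):
            region = by_id[region_id]
            for read_id, calls in read_calls[region_id].reads:
                idxs = sorted(calls)
                ref_start = region.cpg_positions[idxs[0]]
                ref_end = region.cpg_positions[idxs[-1]] + 2
                seq = []
                xm = []
                for pos in range(ref_start, ref_end):
                    idx = region.cpg_index(pos)
                    if idx is not None and idx in calls:
                        if calls[idx] == 1:
                            seq.append("C")
                            xm.append("Z")
                        else:
                            seq.append("T")
                            xm.append("z")
                    elif pos - 1 in region.cpg_positions:
                        seq.append("G")
                        xm.append(".")
                    else:
                        seq.append("A")
                        xm.append(".")
                rows.append(
                    (
                        ref_start,
                        f"{read_id}\t0\t{SIM_CHROM}\t{ref_start + 1}\t42\t"
                        f"{len(seq)}M\t*\t0\t0\t{''.join(seq)}\t"
                        f"{'I' * len(seq)}\tXM:Z:{''.join(xm)}\n",
                    )
                )
        for _, row in sorted(rows):
            fh.write(row)


def write_truth_tsv(scenario: SimScenario, path: str) -> None:
    """Planted truth: templates and modes per region and sample."""
    with open(path, "w") as fh:
        fh.write("region_id\tsample_id\tt1\tt2\tplanted_mhm\tis_planted_dmr\n")
        for rec in scenario.truth:
            for sample in scenario.sample_ids:
                t1, t2 = rec.templates[sample]
                fh.write(
                    f"{rec.region_id}\t{sample}\t{t1}\t{t2}\t"
                    f"{rec.planted_mhm[sample]}\t{int(rec.is_planted_dmr)}\n"
                )
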