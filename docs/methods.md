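# Methods

## Model and assumptions

A diploid genome carries two methylation states per CpG site, one per
homologous chromosome. Within a CpG-dense region, single bisulfite reads
derive from one homolog and report several CpG statuses jointly, so the
co-occurrence of statuses along reads identifies which homolog a status
belongs to — without any genetic (SNP) information. The method assumes:

* each read originates from exactly one homolog;
* within a region each homolog has a single, stable methylation string
  (cell-population heterogeneity beyond the two homolog states is not
  modelled);
* call errors (sequencing and incomplete bisulfite conversion) are
  independent across calls;
* both homologs are sequenced at similar depth.

Hemimethylation is out of scope: both strands' evidence for a CpG is
merged into one site keyed by the forward-strand C coordinate.

## Candidate regions

Regions are generated from the genome alone. Islands with n ≥ 7
contained CpGs are partitioned into floor(n/7) consecutive blocks whose
sizes differ by at most one (each therefore ≥ 7); this balanced scheme
keeps per-region CpG counts in the 7–13 range typical of island
sub-regions. Outside islands, maximal runs of CpGs with consecutive
start-coordinate differences ≤ 20 bp are kept when they hold ≥ 7 sites;
runs longer than 14 sites are split with the same balanced scheme so that
region lengths stay bounded (~90 bp scale). Runs never extend across an
island interval, which guarantees island- and cluster-derived regions are
disjoint. Coordinates are 0-based half-open; a region spans its first CpG
to two bases past its last CpG's C.

## Site classification

Parameters (config keys of `zygosity`):

| parameter | default | meaning |
|---|---|---|
| `th_dp` | 10 | minimum site depth; sites below are uncovered |
| `min_pattern_freq` | 2 | minimum joint-pattern count to survive filtering |
| `single_ratio` | 0.6 | top-pattern share of total for a single true pattern (strict >) |
| `second_ratio` | 0.4 | second/top ratio admitting two true patterns (≥) |

`th_dp = 10` makes the candidate-heterozygous rule require ≥ 5
observations per status, a sensible floor at typical 30× WGBS depth. A
two-status site whose minor status falls below th_dp/2 is called
homozygous for the major status (the minor reads being error-like); an
exact tie below the threshold is filtered (with the default even
threshold this situation implies sub-threshold depth anyway).

Neighbouring candidate heterozygous sites are resolved pairwise left to
right. The confidence of a pair is the total frequency of its true
patterns divided by the maximum depth among the three sites of the
current triple; at the first pair of a region no third site exists yet
and the maximum is taken over the two sites. When the earlier pair's
confidence is greater or equal, the shared site keeps its class and the
new site's class is derived from the new pair's patterns restricted to
those compatible with the shared site; otherwise the shared site is
revised from the new pair, and any earlier phase link that contradicts
the revision is dropped. Revisions are not back-propagated to earlier
pairs. A region's single isolated candidate site, and any pair whose
pattern selection is unresolvable (no pattern surviving the frequency
filter, a three-way tie for the maximum, or tied runners-up), remain
ambiguous: they neither break the region nor appear in the haplotype —
they are simply uncovered.

Tie-break conventions in pattern selection: "above 0.6" is strict,
"not less than 0.4" is inclusive; two patterns tied for the maximum are
accepted as the top two (their ratio is 1) unless a third ties them.

## Haplotype construction

Heterozygous sites are chained through their two-pattern
(anti-correlated) phase links; haplotype 1 takes the smaller status at
the first chain site, so homolog naming is deterministic but arbitrary —
all downstream quantities are invariant under swapping the two strings.
If the chain breaks (a missing or non-informative link), the longest
prefix is kept and the remaining heterozygous sites stay uncovered.
Homozygous sites contribute their status to both strings. MH levels are
computed over covered sites only: uncovered sites are excluded from the
strings rather than encoded as a third symbol, so the level is always a
fraction of an observed 0–1 string. Validity (> 3 covered CpGs) is a
property of the pair, both strings sharing one covered set by
construction.

The mode (MHM) is written higher-MH label first; since both labels are
functions of MH on the same covered set, equal levels give equal labels
and the ordering is unambiguous. Consistency metrics are CpG-weighted:
regions with more covered CpGs contribute proportionally more.

## DMR calling

Two groups are compared per region through their valid haplotype pairs;
multi-sample groups are summarised by the mean of the higher-MH and the
mean of the lower-MH levels across samples (the two-sample comparison is
the primary, fully tested path). Identical modes short-circuit to
non-DMR with no test. The MHD statistic pairs higher with higher and
lower with lower; when the two levels within a group are equal, either
pairing gives the same value.

No distributional test for haplotype-mode differences exists, so
significance uses a read-label permutation test, the natural choice for
a statistic defined on reconstructed haplotypes: pooled reads are
reassigned to pseudo-samples preserving the original sizes, pairs are
rebuilt and MHD recomputed; p = (1 + #{MHD_perm ≥ MHD_obs}) / (1 + n_perm)
with the add-one correction, n_perm = 200 by default (resolution
~0.005, adequate for a 0.05 threshold). Permutations whose pseudo-samples
yield no valid pair score MHD 0; if no permutation yields a valid pair
the region's p is 1 with a degeneracy flag. The permutation test is run
only for regions that already differ in mode with MHD above the
threshold — other regions cannot become DMRs, so their p-value is
reported as missing. Raw p-values are thresholded at 0.05 by default;
Benjamini–Hochberg adjustment is available (`bh_fdr`) but off by
default. DMR types are assigned with precedence 1 > 2 > 3 > 4, which
places pairs satisfying several surface readings (e.g. HL vs HH) under
the hypomethylation-vs-non-hypomethylation type.

## Synthetic data generator

The simulator emulates: two homolog template strings per region, reads
drawn from one homolog covering a contiguous CpG window, and independent
per-call errors. Defaults: 200 regions of 10 CpGs spaced 8 bp (~74 bp
regions, matching the ~90 bp scale of real candidate regions), depth 30
per homolog, error rate 0.01, read span 10 CpGs. The span default
reflects read lengths: a 100–150 bp WGBS read covers a ~74 bp region
entirely. Exactly `depth` reads are drawn per homolog — the two homologs
of a diploid sample are sequenced at the same expected coverage and
depth is parameterised per homolog. Scenario templates are fully hypo-
or hypermethylated per region (CpG islands are predominantly bimodal),
which makes expected consistency and planted DMR counts exact by
construction.

What the generator does **not** emulate: nucleotide-level errors and
mapping ambiguity (reads are simulated at the CpG-call level, with an
optional SAM rendering for parser testing), PCR duplicates, coverage
bias, cell-population epialleles, partial methylation gradients, or
homolog-coverage skew. Passing tests therefore demonstrate correctness
of the reconstruction and calling logic under the stated read model, not
robustness to alignment artefacts or population heterogeneity in real
WGBS libraries.

## Numerical and implementation choices

* Problem sizes in tests and the acceptance script (200-region
  scenarios, 500-region DMR panels, 100–1000-draw oracle comparisons)
  are chosen to make stochastic bounds sharp at desk scale while keeping
  the full suite fast.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; fixed seeds give byte-identical outputs end to end.
* Mate-overlap policy in the alignment parser: the first-encountered
  mate wins and conflicts are counted, so a fragment never contributes
  depth twice. Mapping-quality filtering defaults to 0 (permissive).
* Pattern strings are ordered (status at the left site first): "01" and
  "10" are distinct patterns.

## Known limitations

* The left-to-right sweep is greedy; a revised shared site does not
  trigger re-evaluation of earlier pairs.
* Haplotypes are not linked across regions, and homologs are not
  assigned to parental origin.
* The permutation test assumes exchangeable reads between samples under
  the null (equal library characteristics); strong depth imbalance
  between samples weakens it.
* Consistency ratios are undefined (reported missing) in scopes with no
  valid haplotype pair.
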