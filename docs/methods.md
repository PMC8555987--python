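# Methods

## Problem and model

A small minority of IAP-like retrotransposon copies are variably methylated
(VM): their DNA methylation differs between genetically identical
individuals yet is coherent across an individual's tissues, the behaviour
of a metastable epiallele. The working model implemented here has two
ingredients. First, *sequence*: KZFP proteins recognise their targets
sequence-specifically, so copies carrying diagnostic substitutions — a
sequence clade — can lose KZFP/KAP1 recruitment and with it the
H3K9me3/DNA-methylation silencing it scaffolds. Second, *context*: among
copies with permissive sequence, only those residing in constitutively open
chromatin (near constitutively expressed genes or enhancers) actually
escape; the rest are silenced by heterochromatin spreading. Escaped copies
with high CpG density can then recruit ZF-CxxC readers (CFP1, TET1) that
maintain hypomethylation, and in KAP1-haploinsufficient animals such
CpG-dense young elements gain novel H3K4me3 peaks.

The package does not model these mechanisms generatively beyond what is
needed to test the analysis chain; it implements the measurements.

## Coordinates and missing data

All intervals are 0-based half-open; RepeatMasker `.out` (1-based
inclusive, `C` = minus strand) is converted at the parser boundary.
Methylation positions index the C of the CpG on the plus strand, with
strand-collapsed counts assumed pre-merged. In projected signal matrices a
gap column is MISSING (NaN), never 0, and every mean is missing-aware:
a gap means the copy has no base there, not that it has no signal.

## Alignment and clade calling

The conventional external chain (MAFFT alignment, trimAl trimming, PhyML
tree) is replaced by an in-repo, oracle-testable equivalent, a deliberate
design decision: the tree is used only to delineate sequence clades, and a
transparent method that a brute-force enumeration can verify is preferable
at this scale to an external binary.

- Pairwise and profile–profile alignment: global Needleman–Wunsch, match
  +1, mismatch −1, linear gap −2, `N` scoring as a mismatch against
  everything. Column-vs-column scores are summed pairwise symbol scores
  (equal to the mean up to a constant factor, which cannot change the
  optimum); run on integer-scaled counts every DP comparison is exact and
  the traceback tie order (diagonal > up > left) is deterministic.
- Guide tree: UPGMA on k-mer (k = 6) Jaccard distances.
- Trimming: columns with non-gap occupancy strictly below 10 % are
  removed; `column_map` records the surviving columns' pre-trim indices so
  signal projection (done base-wise on the untrimmed alignment) can be
  subset afterwards — trimming discards columns, not bases.
- Distances and tree: p-distance over columns where both rows are non-gap
  (pairs with < 20 comparable columns are flagged), then UPGMA with
  size-weighted averaging, merge height d/2, ties to the lowest index pair.
- Clades: the k − 1 highest merges are cut; the components below are the
  clades, labelled by smallest member index. k is a user parameter (clade
  boundaries are an empirical choice in this kind of analysis); the
  synthetic default is k = 4 for the LTR set.

Linear rather than affine gaps is a conscious simplification: the planted
regime is substitution-dominated, and a linear scheme keeps the
brute-force oracle exact. Known limitation: on heavily indel-diverged real
families, progressive alignment under a linear gap penalty will fragment
gaps more than MAFFT would, and p-distance + UPGMA is not a maximum
likelihood phylogeny — clade calls, not branch lengths, are the supported
output.

## Element selection rules

LTR copies qualify at length strictly greater than 300 bp. "Flanked"
internal elements — undefined numerically in the motivating analyses — are
internals with a same-strand target-subfamily LTR on their 5′ side within
≤ 25 bp (configurable); LTR–internal junctions are contiguous in intact
proviruses and the tolerance absorbs annotation fragmentation. Each
RepeatMasker row is one instance; fragments are not merged (solo LTRs and
proviral LTRs are treated independently). Sequences with > 10 % N are
dropped. Internals shorter than the 150 bp extraction window are excluded
and reported.

## CpG scoring

`O/E = n_CpG · N / (n_C · n_G)` over a window of length N. Window sweep:
offsets 0, 10, 20, … while the 200 bp window fits, plus one end-anchored
window so the 3′ end is never unscored; elements at or below 200 bp get a
single whole-element window (N = element length). Both end-handling rules
are package decisions where the source procedure is silent. Masked or
ambiguous bases count as non-C/G. Subfamily summaries drop subfamilies
with fewer than 50 copies (default; the "low copy number" cut-off is not
numerically specified in the motivating work), and an element is VM if it
overlaps a VM locus by ≥ 1 bp. Background scores use uniformly placed,
length-matched random intervals, rejecting draws that run off a
chromosome; note that for elements much longer than the window the
max-window statistic exceeds 1 even on random sequence (a maximum over
many windows), so backgrounds are always compared at matched lengths.

## Context, conservation, methylation, peaks

- Context: "within 50 kb" is ≤ 50 000, "less than 1 kb" is < 1 000 — both
  literal readings; gene rule takes precedence so classes are disjoint.
  Distances are edge-to-edge to gene bodies, not TSSs. Constitutive
  expression: FPKM > 2 in > 90 % of samples, both strict (10/11 samples
  qualifies, 9/10 does not).
- Conservation: "fully deleted" requires a single deletion record to
  contain the element; adjacent deletions jointly covering it do not count
  (per-feature `-f 1.0` semantics). Branch presence is an OR over member
  strains; a copy is polymorphic if absent from ≥ 1 branch.
- Methylation: per-CpG fractions averaged unweighted over CpGs with
  coverage strictly > 5 reads; a region with no retained CpG is UNDEFINED
  and excluded from tests (and counted), never imputed as 0.
- Peaks: replicate sets are union-merged into maximal intervals; support is
  the number of distinct replicates overlapping the merged interval; kept
  at support ≥ 2 and dropped if touching an exclusion ("dead-zone") set.
  Novel peaks in the mutant genotype must have zero overlap with any
  wild-type merged peak and mean-coverage ratio
  (mut + 0.5)/(wt + 0.5) ≥ 3; the pseudocount handles zero wild-type
  signal, and means (not totals) make the rule length-invariant.
- Statistics: Fisher's exact and Wilcoxon rank-sum delegate to scipy
  (two-sided probability-mass summation; exact rank-sum enumeration when
  n ≤ 20 without ties, else normal approximation with tie and continuity
  corrections); the test suite holds both against independent
  full-enumeration oracles. Odds ratios use Haldane's +0.5 correction when
  a cell is zero. Age enrichment resamples R = 1000 (pipeline default 500)
  sets of length-matched uniform random loci; each locus is assigned to
  its largest-overlap element (ties to the leftmost), then to that
  subfamily's age bin; O/E is observed over null mean with an empirical
  95 % interval. No gap/blacklist masking is applied to the null (an
  optional exclusion set can be supplied).

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the structure the pipeline is meant to
recover, at fixed default conditions: 4 clades × 50 LTR copies of a 330 bp
consensus; 8 diagnostic substitutions per clade (disjoint sites, so clade
pairs differ at ~16 sites); within-clade divergence 0.02 substitutions per
bp; 5 proviruses per clade (5′LTR–internal–3′LTR with ≤ 10 bp gaps)
consuming two LTR copies each; roughly half of all copies inserted on the
minus strand as reverse complements. The consensus is CpG-enriched
(O/E ≈ 1.5, IAP-like) against a CpG-depleted background (O/E ≈ 0.25,
genome-like). The last clade is the escape clade: lowest KZFP/KAP1 profile
heights (Poisson counting noise per bp, zero background so tracks compress
well), variable-or-escaped methylation (VM probability 0.5), and the
highest per-strain deletion probability (0.30 vs 0.05). Methylation:
silenced copies draw per-CpG levels near 0.85 (SD 0.05), escaped near
0.10, VM copies draw one uniform [0.1, 0.9] level per copy per individual
shared across that copy's CpGs — the coherent-epiallele property; read
depths are Poisson(20), so the > 5× filter bites occasionally. Context
classes are planted with probabilities 0.83/0.17 (VM:
constitutive/enhancer) and 0.12/0.07/0.81 (non-VM), and genes/enhancers
are placed to make the class hold by construction; copies sit one per
110 kb slot (jitter ± 5 kb, gene offsets ≤ 30 kb) so a neighbour's gene
can never leak into another copy's 50 kb radius. Eight strains form four
two-strain branches. Twelve escaped copies carry mutant-only peaks in ≥ 2
of 3 replicates at ≥ 3× coverage; 40 background peaks are shared by both
genotypes. Twelve extra low-copy subfamilies with graded CpG density, plus
subfamily age and differential-expression tables (high-CpG subfamilies
responsive), feed the age-enrichment and expression analyses.

One root seed derives fixed per-stage substreams, so any stage regenerates
independently and all outputs are byte-identical under a fixed seed.

What the generator does not emulate — and hence what green tests do not
establish about real data: read-level noise and mapping ambiguity (signal
is planted directly as coverage), indels within elements (clades differ by
substitutions only, flattering the linear-gap aligner), overlapping or
nested repeat annotations, non-uniform genomic backgrounds (GC isochores,
assembly gaps) that bias the resampling null, tissue differences, and any
mechanistic coupling between binding loss and methylation beyond the
planted labels.

## Problem sizes and numerics

Default analyses run on the 200-copy, ~21 Mb synthetic genome: the full
simulate-and-analyse cycle takes a few seconds on one CPU, and the
package's own verification (oracle sweeps over all 2×2 tables with
total ≤ 40, 500 random UPGMA instances, 1000-replicate resampling nulls)
runs in about two minutes. Alignment DP is exact on scaled integers;
p-distances and UPGMA operate in float64 with symmetric-input validation;
Fisher ties are resolved at scipy's 1e-7 relative tolerance; resampling
quantiles are empirical (2.5/97.5 %). Degenerate inputs fail loudly:
empty sequences, all-trimmed alignments, row pairs with zero comparable
columns, zero-margin contingency tables (p = 1 by convention), regions
with no retained CpGs (UNDEFINED), and configurations whose genome cannot
hold the requested placements all raise with a stage- or rule-naming
message.
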