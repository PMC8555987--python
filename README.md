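# vmte — variably methylated transposable elements

Tools for asking why some copies of a transposable-element family escape
DNA-methylation silencing while near-identical copies stay silenced.
Intracisternal A-particles (IAPs), a young family of mouse endogenous
retroviruses, are the motivating case: a handful of IAP long terminal
repeats (LTRs) are *variably methylated* (VM) — methylation differs between
genetically identical individuals but is consistent across tissues within
one individual. `vmte` implements, as one tested pipeline, the analyses
that connect this behaviour to sequence and context:

- **Sequence clades.** LTR copies (> 300 bp, strict) and the first 150 bp of
  internal elements flanked by a target LTR are multiple-aligned
  (progressive profile alignment over a k-mer UPGMA guide tree), trimmed of
  columns with < 10 % occupancy, and clustered (p-distance + UPGMA); clades
  are cut from the k − 1 highest merges, with k chosen by the user.
- **Signal projection.** Per-base KZFP/KAP1 (or any) coverage is projected
  into alignment-column coordinates — copy j's i-th base lands in the column
  holding row j's i-th non-gap symbol; gaps are missing data, never zero —
  so binding can be averaged across copies and compared between clades.
- **CpG density.** Per element, the observed/expected CpG ratio
  `O/E = n_CpG · N / (n_C · n_G)` is maximised over 200 bp windows slid in
  10 bp steps, and compared per subfamily with VM-overlap fractions and
  against length-matched random genomic background.
- **Genomic context.** Elements are classified as within 50 kb (inclusive)
  of a constitutively expressed gene (FPKM > 2 in > 90 % of samples, both
  strict), else within < 1 kb of an enhancer, else distal.
- **Strain polymorphism.** A copy is absent in a strain only if a single
  structural-variant deletion contains 100 % of it (`intersect -f 1.0`
  semantics); strains collapse into phylogeny branches by an any-member
  rule, and per-clade polymorphism rates follow.
- **Methylation and peaks.** Per-element methylation averages per-CpG
  fractions with coverage strictly > 5 reads; replicate peak sets are
  union-merged and kept at support ≥ 2; "novel" peaks in a mutant genotype
  must not touch any wild-type peak and need ≥ 3× wild-type signal.
- **Statistics.** Fisher's exact test (two-sided) for clade × VM
  enrichment, Wilcoxon rank-sum for group comparisons, and an
  observed/expected age enrichment built from R resamplings of
  length-matched random loci.

Because the original inputs are genome-scale external datasets, the package
ships a first-class synthetic-data generator (`vmte.synthetic_data`) that
emulates every input format with planted ground truth — sequence clades,
clade-dependent binding, silenced/variable/escaped methylation regimes,
context placement, strain-biased deletions, genotype-dependent peaks — so
the whole pipeline is exercisable and testable offline.

## Worked example

```bash
vmte simulate --seed 1 --outdir demo
vmte run --config demo/config.yaml
```

The first command writes a ~21 Mb two-chromosome genome with 200 LTR copies
in 4 planted clades (50 each), binding tracks, methylation calls for 8
individuals, genes/enhancers, 8 strains' deletions, and peak sets, plus
`truth.json`. The second prints the analysis summary; with seed 1 the key
lines are:

```
"clade_sizes": {"clade1": 50, "clade2": 50, "clade3": 50, "clade4": 50},
"lowest_signal_clade": {"KZFP": "clade1", "KAP1": "clade1"},
"most_vm_enriched_clade": "clade1",
"vm_enrichment_p": 2.7956352370779747e-18,
"vm_enrichment_or": 301.0,
"most_polymorphic_clade": "clade1",
"vm_methylation_sd": 0.218..., "non_vm_methylation_sd": 0.014...,
"n_novel_peaks": 12
```

Read: clustering recovered the four planted clades exactly; the clade
labelled `clade1` in this run is the planted escape clade — weakest
KZFP/KAP1 signal, strongly VM-enriched (Fisher OR 301, p ≈ 3 × 10⁻¹⁸), the
most deletion-polymorphic across strains — VM copies vary across
individuals (SD 0.22 vs 0.01 for silenced copies), and all 12 planted
mutant-only H3K4me3 loci were found. Per-stage tables land in
`demo/results/`.

Per-stage subcommands (`extract-seqs`, `clades`, `project`, `cpg`,
`context`, `conservation`, `enrich`, …) expose the same library functions
individually; see `vmte --help`.

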