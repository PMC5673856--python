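# treedelim

Gene-tree species-delimitation statistics and grouped sequence distances
for haplogroup-level taxonomy testing, with a multispecies-coalescent
synthetic-data generator so every pipeline stage is testable offline.

Given (a) a rooted, support-annotated phylogeny (newick), (b) a tip →
haplogroup assignment table (TSV) and (c) a DNA alignment (FASTA), the
package computes:

- **treeio** — newick parsing/writing (numeric internal labels are nodal
  support), patristic distance matrices, MRCA, monophyly tests against a
  putative taxonomy, and bootstrap/posterior support categorization.
- **delimitation** — per-haplogroup statistics: Intra, Inter + closest
  haplogroup, Intra/Inter, Av(MRCA-tips), and seeded Monte-Carlo
  P ID (strict/liberal) identification probabilities with 95% CIs; column
  means with NA exclusion; TSV reports.
- **seqdist** — uncorrected-p, Kimura 2-parameter and GTR-corrected
  pairwise distances under pairwise deletion; within/between-haplogroup
  distance matrices (diagonal = within p, lower = between p, upper = K2P,
  percent units); substitution-saturation profiles; missing-data fraction.
- **synthetic** — multispecies-coalescent gene trees (msprime) and
  K2P(+Γ+I) sequence evolution with controlled missing data; presets
  `deer-like` (17 haplogroups, 1–20 tips each, transition-biased, 11%
  missing), `deep` (clean monophyly) and `shallow` (incomplete lineage
  sorting).
- **datasets** — bundled published reference tables (two 17-haplogroup
  delimitation tables and the matching grouped distance matrix) used for
  desk-scale validation.

## CLI

```sh
# simulate a dataset (tree.nwk, alignment.fasta, assignments.tsv, truth.json)
treedelim simulate --preset deer-like --seed 1 --out data/

# per-haplogroup delimitation report + column-mean summary
treedelim delimit --tree data/tree.nwk --groups data/assignments.tsv \
    --support-kind bootstrap --pid-reps 1000 --seed 1 --out out/

# grouped p/K2P matrix (percent) + saturation profile
treedelim distances --aln data/alignment.fasta --groups data/assignments.tsv \
    --out out/

# both at once
treedelim report --tree data/tree.nwk --aln data/alignment.fasta \
    --groups data/assignments.tsv --out out/
```

All reports are TSV with the literal `NA` for undefined cells (singleton
haplogroups, saturated pairs); causes are logged to stderr.  A YAML file
passed via `--config` overrides flag defaults.

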