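# metapep

Spectral-count metaproteome profiling of faecal microbiome cohorts.

Given per-sample tables of identified peptides with spectral counts, a
taxonomy, and peptide-level annotation maps, `metapep` provides:

* **Peptide taxonomy** by the lowest-common-ancestor (LCA) principle, with
  I/L equating and missed-cleavage handling (peptides are split into fully
  tryptic fragments whose matches are combined), plus per-sample domain
  partitioning (bacterial / archaeal / eukaryotic / ambiguous) and
  host-clade ("at least Chordata") peptide subsets.
* **Functional profiles**: spectra summed per KO, COG, COG family or taxon
  rank, taxon-restricted KO profiles, max-per-sample abundance filtering
  ("at least N spectra in one of the samples") and per-sample relative
  percentages.
* **Gut metabolic modules (GMM)**: per-module coverage over alternative
  pathways (within-step alternative KOs collapsed by max), strict
  coverage > 2/3 detection, and median step abundance of the best pathway.
* **Core / rarefaction analysis**: per-subject KO sets and bootstrap
  accumulation and core curves over subject subsets.
* **Comparative statistics**: Jaccard / 1−Pearson complete-linkage sample
  clustering with Newick export, a Spearman human×bacterial KO screen with
  BH (or Storey) q-values, bacterial/eukaryotic ratio trajectories with a
  Fisher exact cluster×group test and a paired Wilcoxon check, Shannon
  diversity, and per-phylum proteome-vs-16S concordance.
* **A synthetic cohort generator** (Dirichlet-multinomial hierarchy) that
  emits every input the pipeline consumes — taxonomy, annotation maps,
  module catalogue, peptide tables, metadata, a matched 16S table — with
  known ground truth: personalised, temporally stable subject profiles, a
  common functional core, ~14% host spectra, <1% archaeal spectra and a
  null treatment effect by default.

All file formats are plain text (TSV, Newick, a small GMM module dialect);
NCBI-style taxdumps (`nodes.dmp`/`names.dmp`) are also accepted.

## CLI

One executable with subcommands; global flags `--config <file>`
(`key = value` lines), `--seed <int>`, `--out <dir>`, `--verbose`.

```sh
# generate a synthetic cohort bundle
metapep --seed 42 --out sim simulate

# LCA assignment and domain fractions
metapep --out run lca --peptides sim/peptides.tsv \
    --taxonomy sim/taxonomy.tsv --map sim/peptide_taxa.tsv

# KO profile, abundance filter, GMM scoring
metapep --out run profile --peptides sim/peptides.tsv --level ko \
    --ko-map sim/peptide_ko.tsv
metapep --out run filter --matrix run/matrix.tsv --min-max-count 5
metapep --out run gmm --modules sim/modules.txt --ko-matrix run/filtered.tsv

# rarefaction, clustering, correlation, concordance, plots
metapep --out run --seed 1 rarefy --ko-matrix run/matrix.tsv \
    --meta sim/metadata.tsv --intervals 2:16 --replicates 1000
metapep --out run cluster --peptides sim/peptides.tsv --distance jaccard
metapep --out run correlate --human human_ko.tsv --bacterial bact_ko.tsv
metapep --out run concordance --proteome phyla.tsv --sixteen-s sim/sixteen_s_phyla.tsv
metapep --out run report --matrix run/matrix.tsv
```

## GMM module file dialect

```
MF0001<TAB>module name
K00001,K00002      # step 1: alternative KOs
K00003             # step 2
//                 # next alternative pathway
K00004
///                # end of module
```
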