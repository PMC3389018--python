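# fermgenomics

Fermentation genomics for *Lactobacillus plantarum*: a tested, reusable
pipeline that links controlled fermentation conditions to the physiology
and the transcriptome of a batch culture.

## The problem

Industrial lactic-acid-bacteria strains are usually improved by comparing
*different strains* (genotype–phenotype matching), which says nothing about
how *conserved* genes respond to process conditions. The complementary
approach implemented here grows **one** strain under a balanced fractional
factorial design over five fermentation factors — temperature (28/37 °C),
pH (5.2/5.8/6.4), NaCl (0/300 mM), amino-acid dose (1.1/2.0×), and sparging
gas (N₂/air) — then asks three questions:

1. which factors move which physiological phenotypes (µ_max, OD_max, six
   organic acids)?
2. which transcripts track which phenotypes?
3. which genes respond to which factors, and what regulatory structure
   (shared responses, promoter motifs) explains those responses?

The package ships the 30-fermentor design/phenotype table as a fixture and
a synthetic-data generator that emulates the full study (≈3099 genes × 29
profiled fermentations) with *known planted structure*, so every analysis
stage is testable end to end without any external download.

## Methods at the core

- **Mann–Whitney U screen** (`pheno_screen`): each factor contrast × each
  phenotype, exact enumeration for small tie-free samples, BH-FDR over the
  whole grid, direction from group medians.
- **Regularized t-test** (`diffexpr`): per-gene variance shrunk toward the
  mean pooled variance of a 101-gene window along the expression rank,
  s²_reg = (λ·s²_bg + (n_A+n_B−2)·s²_pooled)/(λ + n_A + n_B − 2) with
  λ = 10 pseudo-observations and df = λ + n_A + n_B − 2; ratios are
  2^(mean_A − mean_B); BH-FDR per contrast.
- **Random-forest association** (`rf_assoc`): metabolite phenotypes
  dichotomized into low/high classes, 1000-tree Gini forests on the
  transcriptome, genes ranked by mean-decrease-Gini importance, top-k
  overlap across phenotypes.
- **Iterative grouped-gene growth signature** (`growth_signature`): score
  gene groups of size k (k = 1, 2, …) by the Pearson correlation of their
  average expression with µ_max, keep the genes of the 300 best groups as
  the next pool, and stop when the pool stops shrinking.
- **Response clouds and network** (`cloud_network`): genes with q < 0.05
  and fold change > 1.5 per factor, split by direction, assembled into a
  Cytoscape-compatible factor→gene network (SIF/GraphML) with
  single/shared-response partitioning and hypergeometric class enrichment.
- **Inverted-repeat motif discovery** (`ir_motif`): enumerate candidate
  arm–spacer–revcomp(arm) repeats in foreground promoters, score
  presence/absence enrichment against background promoters with the
  hypergeometric upper tail, and report PWMs with per-column information
  content. The oxygen-response site TTGTGCACAA is its own reverse
  complement — a perfect inverted repeat.
- **Two-channel array preprocessing** (`array_prep`): per-array lowess
  detrending of M = log2(cy5/cy3) vs mean intensity, inter-slide scaling to
  a common total signal, and median probe→gene collapse.

## Worked example

```python
import fermgenomics as fg

table = fg.load_table1()                      # the packaged 30-fermentor design
count, _ = fg.distinct_conditions(table)      # -> 24 distinct conditions
mu = fg.phenotype_range(table, "mu_max")      # -> (0.23, 0.80), fastest F1

screen = fg.phenotype_screen(table)
print(screen.cell("T", "mu_max"))             # temperature vs growth rate
print(screen.cell("NaCl", "od_max"))          # salt vs biomass yield
```

prints (among the 7 comparisons × 2 phenotypes of the screen):

```
fermentors: 30, distinct conditions: 24
mu_max range: 0.23-0.8 /h (fastest: F1)
T  vs mu_max:  U=15.0,  p=0.0001, q=0.0008, direction=+
NaCl vs od_max: U=163.5, p=0.0280, q=0.0783, direction=-
```

i.e. cultures at 37 °C grow significantly faster than at 28 °C, and added
NaCl lowers the final biomass yield. On a simulated study with a planted
47-gene growth-rate signature:

```python
from fermgenomics.synthetic_data import SimulationConfig, simulate_study

sim = simulate_study(SimulationConfig(seed=1))
mumax = sim.study.phenotype_series("mu_max", list(sim.expression.columns))
trace = fg.iterate_signature(sim.expression, mumax, seed=1)
```

recovers a 45-gene set in 4 iterations with Pearson r = 0.999 (Spearman
0.997) between its average expression and µ_max, at Jaccard 0.96 against
the planted truth.

## Command-line pipeline

A config-driven project store replaces the original study's database
service: each stage reads and writes plain TSV/FASTA/JSON files and records
a manifest with parameter and checksum provenance.

```sh
fermgenomics all --config project.yaml --seed 1
```

with verbs `simulate`, `prep`, `de`, `screen`, `rf`, `signature`,
`network`, `enrich`, `motif`, `all` and common flags `--config`, `--seed`,
`--out`, `--log-level`.

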