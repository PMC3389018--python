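# Methods

This note documents the models and procedures implemented in
`fermgenomics`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Study model

A study is a table of batch fermentors, each described by five categorical
condition factors — NaCl (0/300 mM), amino-acid dose (1.1/2.0× standard),
temperature (28/37 °C), pH (5.2/5.8/6.4), sparging gas (N₂/O₂) — and
endpoint phenotypes: maximum specific growth rate µ_max (h⁻¹), maximum
optical density OD_max (OD600), and optionally six organic-acid
concentrations (mM). Condition levels are compared as exact printed values,
not within floating-point tolerances: they are design codes. The packaged
30-fermentor table follows a balanced fractional factorial layout with 24
distinct condition combinations plus replicated controls; its fermentor
F30, sampled only at stationary phase, carries a flag that excludes it from
transcriptome-linked analyses while keeping it in phenotype-only ones.
Design balance is audited by counting distinct design points per factor
level and flagging pairwise level combinations never realised — the
signature of confounding in a fractional design.

## Array preprocessing

Raw two-channel probe intensities are processed in three steps:

1. **Lowess detrending** per array: M = log2(cy5/cy3) regressed on
   A = (log2 cy5 + log2 cy3)/2 with lowess (span 0.4, tricube weights, 3
   robustness iterations — conventional values); the fitted trend is
   subtracted from M and split evenly between the channels, so A is
   preserved per probe. A constant dye bias is removed exactly.
2. **Inter-slide scaling**: one multiplicative factor per array equalises
   total linear signal across arrays; the target is the geometric mean of
   the observed totals (so the correction is symmetric in log space).
   Whether the original correction used totals or means, linear or log
   scale, is not recoverable; linear totals with a geometric-mean target is
   the recorded choice.
3. **Probe→gene collapse**: the per-probe abundance is the mean of the two
   channels' log2 values, and the gene value per array is the median over
   the gene's probes (even count → mean of the two middle values).

No dye-swap/loop linear modelling is performed: after normalization each
array contributes absolute per-gene log2 levels, which is the
representation all downstream stages consume.

## Regularized differential expression

With 2–15 arrays per class, per-gene variances are noisy. The two-class
test shrinks the pooled per-gene variance s²_pooled toward a local
background s²_bg, the mean pooled variance of the 101 genes nearest in
overall mean expression (windows truncate at the extremes):

    s²_reg = (λ·s²_bg + (n_A+n_B−2)·s²_pooled) / (λ + n_A + n_B − 2)

with prior weight λ = 10 pseudo-observations; t uses s²_reg with
df = λ + n_A + n_B − 2, two-sided p from Student's t, and BH-FDR q across
all genes. λ = 0 reduces exactly to the ordinary pooled t-test. Window 101
and λ = 10 are the classic defaults for this family of tests. Under a
global null the test is mildly *conservative* (measured rejection ≈ 0.04
at p < 0.05 over seeded replicates) because the shrunken variance is less
dispersed than a χ² variate with the nominal degrees of freedom; it is
never anti-conservative, and BH discoveries under the null are typically
zero. Replicate fermentations are treated as independent samples within
their class; no dye covariate is modelled.

## Phenotype screen

Seven comparisons (the four two-level factors plus the three pairwise pH
contrasts) × all phenotypes with data. Tests are two-sided Mann–Whitney U:
exact enumeration when the pooled sample is ≤ 12 and tie-free, otherwise
the tie-corrected normal approximation. U is reported for the first group;
direction is `+` when the second (higher) level has the higher median,
undefined on tied medians — direction is reported separately rather than
folded into one-sided tests. The BH family is the whole screen grid (a
per-phenotype family is configurable); whether the original analysis
corrected within rows, columns or globally is unstated, so the global
family is the recorded choice.

## Random-forest metabolite association

A continuous acid phenotype is split into low/high classes — by default at
the median (values ≤ median → low), configurable to extreme tertiles,
which drops the ambiguous middle third. A 1000-tree random-forest
classifier (Gini impurity, √p features per split, fixed seed) is trained
with genes as predictors, and genes are ranked by mean-decrease-Gini
importance. Cross-phenotype agreement is summarised two ways: the overlap
of top-k importance sets, and the significance/direction concordance of
two differential-expression runs on the same class splits.

For the citrate/succinate recovery experiment (both acids driven by one
latent "conversion activity"), the **extreme-tertile split is the
appropriate class design**: a median split of a continuous unimodal latent
necessarily assigns near-boundary samples arbitrarily, and with only 29
samples a handful of soft labels is enough to let chance genes displace
genuinely associated ones from the top 10. Dropping the middle third
restores reliable recovery (planted 5-gene set fully inside both top-10s
in ~9/10 seeded studies vs ~5/10 with the median split).

## Iterative grouped-gene growth signature

Single transcripts correlate weakly with µ_max at array noise levels;
averaging a well-chosen group suppresses independent noise. The procedure:

- iteration k scores groups of k genes by |Pearson r| between the group's
  per-fermentation average expression and µ_max (absolute value, so
  strongly anti-correlated groups survive; the sign is reported);
- the union of genes in the top 300 groups becomes the next pool;
- k increases by one per iteration; iteration stops when the pool fails to
  shrink (the previous, smaller pool is returned) or k exceeds the pool.

"Groups" are k-subsets of the current pool: enumeration is exhaustive
while C(pool, k) ≤ 200 000 and otherwise a seeded uniform sample of
200 000 subsets. This reproduces the single-gene top-300 behaviour at
k = 1 exactly and stays tractable at larger k; with exhaustive enumeration
the result is seed-independent. Both Pearson and Spearman correlations of
the final averaged set are reported. On default synthetic studies the
procedure converges in ~4 iterations and recovers the planted 47-gene
signature at Jaccard ≈ 0.9 with r ≈ 0.99.

## Response clouds, network, enrichment

A gene joins a factor's response cloud when q < 0.05 *and*
max(ratio, 1/ratio) > 1.5; direction follows the ratio. The procedural
fold threshold is 1.5 (a stricter 2.0 appears in some renderings of the
same analysis; `fold_min` is therefore an explicit, documented parameter).
The three pH contrasts collapse to one pH node: a gene is pH-responsive if
it passes thresholds in any pair, with direction taken from the extreme
5.2-vs-6.4 contrast. Cloud members partition by the exact set of factors
they respond to (single vs shared responses); the factor→gene network
exports to Cytoscape SIF (`responds_up`/`responds_down` relations) and
GraphML (direction and group attributes), and re-imports losslessly.
Functional overrepresentation of any gene set uses the hypergeometric
upper tail P[X ≥ k] over a flat gene→class map — no ontology-graph
propagation, matching the flat functional classification used for this
organism — with BH correction across classes.

## Inverted-repeat motif discovery

Candidates are arm + N^spacer + revcomp(arm) for arm lengths 4–7 and
spacers 0–6, enumerated from arms observed in foreground promoters.
Scoring is presence/absence per promoter (a promoter either carries the
site or not), by hypergeometric upper-tail enrichment of foreground
presence against the pooled foreground+background set; candidates must hit
≥ 30 % of foreground promoters. Because the spacer is a wildcard, the
candidate family is closed under reverse complement, so one forward-strand
scan counts sites on either strand. Near-duplicate candidates (site-set
Jaccard > 0.8) merge into the lowest-p representative, with ties broken
toward the longest arm (the most specific repeat). Each motif carries a
PWM built from its aligned foreground sites with +0.5 pseudocounts and
per-column information content in bits against a uniform background;
log-odds scanning of new sequences reports hits above a configurable
fraction of the maximum attainable score. Upstream regions default to
300 bp, truncated (and flagged) at contig edges.

## Synthetic-data generator

The generator emulates the study's structure: the packaged 30-fermentor
design (29 with transcriptomes), ~3099 genes, and planted structure for
every downstream stage. Defaults, chosen once:

| component | default | rationale |
|---|---|---|
| baseline expression | N(8, 2) log2 per gene | array-intensity scale, exercises intensity-dependent normalization |
| expression noise | 0.5 log2 | moderate array noise |
| responsive sets | 50 up + 50 down per factor (T, pH, NaCl, O₂), effect 2 log2 | amino-acid dose omitted: it showed virtually no transcriptome response |
| shared responses | pH shares 15 up/15 down with temperature | the largest clouds overlap in the real study |
| µ_max signature | 47 genes, 2 log2 per SD of µ_max | the size of the real final gene set |
| metabolite genes | 5 genes, 2 log2 per SD of the conversion latent | the number of shared top-10 genes observed |
| condition→phenotype effects | T→µ_max +0.2 h⁻¹, NaCl→OD_max −0.8, O₂→acetate +5 mM, pH→formate +1.5 mM/step | the study's strongest screen findings, at realistic magnitudes |
| phenotype noise | µ_max 0.05 h⁻¹, OD_max 0.3, acids 0.3–15 mM | measurement-scale |
| conversion latent | NaCl −0.8, spread 0.7; coupling ±3 mM into citrate/succinate | added salt suppresses citrate→succinate conversion |
| promoters | 300 bp uniform-random; TTGTGCACAA core in 80 % of O₂-up promoters, random offset and strand | the discovered oxygen-response repeat |
| probe mode | 3 probes/gene, per-probe affinity SD 0.3, channel noise 0.1, dye-bias slope 0.5 log2 | gives the lowess step a real trend to remove |

One global seed spawns a fixed hierarchy of per-component generator
streams, so adding a component never perturbs the draws of another, and
identical configs are bit-identical.

**What the generator does not emulate.** Expression is Gaussian in log2
with planted effects that are exactly additive; real arrays have
heavy-tailed, intensity-dependent noise and correlated genes. Acids carry
only measurement-scale noise on top of the shared latent, so the
citrate↔succinate anti-correlation comes out near −0.98, stronger than the
≈ −0.8 seen in real fermentations where acid-specific pathway variation
(not modelled) dilutes the coupling. Phenotypes are endpoint values — no
growth kinetics or time series. Passing recovery tests therefore
demonstrates that the algorithms recover their targets under the study's
geometry, sample sizes and noise scales, not that they would perform
identically on arbitrary real data.

## Numerical choices and degenerate inputs

- Ties on phenotype extremes resolve to the first record in table order.
- Dichotomization sends values equal to the median to "low"; a phenotype
  with all values identical is an error (no split exists).
- Group scoring treats zero-variance group averages as correlation 0;
  constant µ_max is an error.
- BH is the standard step-up; q-values are clipped at 1.
- PWM columns always receive +0.5 pseudocounts; `N` bases score 0 in
  log-odds scans, so all-N sequences produce no hits.
- Pipeline stages write outputs into a temporary directory and move them
  into place, and verify input checksums against the manifests of the
  producing stages.

## Problem sizes used in tests and the acceptance script

Null calibration uses 200 simulated null studies for the phenotype screen
and 50 replicate 3099-gene matrices (4 vs 4) for the regularized t;
recovery experiments use the full 3099-gene default study across 5 seeds
(signature) or 10 seeds (random forest, motif null). These sizes give
stable Monte-Carlo estimates while keeping a full run in the minutes
range.

## Known limitations

- The iterative signature's group-formation scheme in the original
  analysis is underdetermined; k-subset sampling is this package's
  reproducible interpretation, and the recovered gene set is accordingly
  not claimed to match any historically reported gene list.
- The exact parameters of the original regularized-t analysis and its
  dye-swap handling are not recoverable; defaults are documented above.
- Motif discovery searches inverted repeats only — no general PWM/EM
  discovery — and emits PWM/IC tables rather than rendered sequence logos.
- The screen does not attempt to reproduce any specific printed p-value
  grid: organic-acid inputs for the real study are not published, and the
  original test conventions (sidedness, FDR family, 29 vs 30 fermentors)
  are unstated.
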