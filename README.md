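# phycoactivity

Toolkit for analysing **total versus active microbial communities** in
cyanobacterial aggregates (CAs) from paired 16S amplicon libraries: the rDNA
library describes the *total* community, the rRNA library (sequenced from
reverse-transcribed rRNA) the *metabolically active* fraction. The package is
aimed at microbial ecologists working with bloom material sampled across
dates and incubation conditions (daytime, nighttime, anoxic).

## What it computes

Given matched rDNA/rRNA ASV count tables, a rooted phylogeny, sample
metadata, and hydrophysicochemical measurements, the pipeline covers:

* **Ingest** — validation, pairing of rDNA/rRNA libraries, rarefaction to a
  common depth (default 21,160 reads) by seeded multivariate-hypergeometric
  subsampling, relative-abundance normalisation. TSV and BIOM 2.1 formats.
* **Diversity** — richness, bias-corrected Chao1, Gini-Simpson; Bray-Curtis
  dissimilarity; principal-coordinate analysis (classical metric scaling
  with negative eigenvalues reported).
* **Relative activity** — the per-taxon ratio of rRNA-based to rDNA-based
  relative abundance. In the log-log abundance scatter, a taxon above the
  1:1 line (ratio > 1) is classified *active*. The core regression is

  `log10(rRNA/rDNA) = a + b · log10(rDNA) + e`

  fitted by OLS over all (taxon, sample-pair) records with both abundances
  non-zero; residuals are then attributed to environmental factors (WT, pH,
  Tur, EC, DO, NO3-N, NO2-N, NH4-N, DIN, DIP) by standardized per-factor
  regressions and by permutation importance around a random-forest
  regressor.
* **Association tests** — Mantel tests between distance matrices, MRPP with
  permutations restricted to strata (sampling dates), paired Wilcoxon tests,
  and Spearman correlation panels with Benjamini-Hochberg adjustment.
* **Community assembly** — abundance-weighted βMNTD (the mean phylogenetic
  distance between nearest relatives across a pair of communities) and its
  standardized effect size βNTI against 999 taxa-label randomizations:

  `βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null)`

  with βNTI < −2 ⇒ homogeneous selection, βNTI > 2 ⇒ heterogeneous
  selection, otherwise stochastic assembly.
* **Synthetic data** — a generator producing paired count tables,
  environmental tables, and Yule phylogenies with known ground truth
  (activity slope, environmental coefficients, assembly mode), used to
  validate every stage without external data.

## Worked example

```python
import phycoactivity as pa

cfg = pa.SimConfig(n_taxa=300, n_dates=17, depth=21160,
                   activity_slope=-0.6, noise_sd=0.3, seed=0)
rdna, rrna, meta, env, tree, truth = pa.simulate_paired_dataset(cfg)

records = pa.compute_activity(pa.relative_abundance(rdna),
                              pa.relative_abundance(rrna),
                              pa.pair_samples(meta))
fit = pa.fit_abundance_activity(records)
print(f"slope={fit.slope:.3f}  R2={fit.r2:.3f}  n={fit.n}")

table, tree2, _ = pa.simulate_assembly_scenario("selection", pa.SimConfig(seed=0))
summary = pa.classify_processes(pa.bnti(table, tree2, n_null=999, seed=0))
print(summary[["group", "n_pairs", "frac_homogeneous_selection"]].to_string(index=False))
```

Output:

```
slope=-0.606  R2=0.641  n=13459
group  n_pairs  frac_homogeneous_selection
  all      105                         1.0
```

The fitted slope recovers the generated abundance-activity exponent (−0.6):
rare taxa are disproportionately active, abundant taxa less so, and rDNA
abundance explains ~64% of the variance in relative activity. The selection
scenario — all communities filtered toward one clade — is classified as
homogeneous selection for every sample pair.

The same stages run from the shell via the `phycoactivity` command
(subcommands `simulate`, `ingest`, `diversity`, `activity`, `associate`,
`assembly`, and `run` for a full YAML-configured pipeline).

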