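# Methods

## The measurement model

Paired 16S libraries are sequenced from the same physical sample: an rDNA
library (gene copies, the total community) and an rRNA library
(reverse-transcribed ribosomes, the active fraction). Both are ASV count
tables over a shared taxon axis. The per-taxon **relative activity** is the
ratio of rRNA-based to rDNA-based relative abundance; ratio > 1 (strictly)
classifies a taxon as active in that sample. The strict inequality means a
point exactly on the 1:1 line of the log-log abundance scatter is *not*
active; with continuous proportions the boundary case has measure zero, so
the choice only matters for constructed data.

Records with a zero in either library are excluded rather than
pseudocounted: a zero in one library of a pair makes the ratio undefined or
infinite, and at a fixed read depth zeros carry information about abundance
that a pseudocount would distort. A pseudocount mode exists
(`compute_activity(..., pseudocount=...)`) for sensitivity analysis only.

## Rarefaction

All samples are subsampled **without replacement** (multivariate
hypergeometric) to a common depth, default 21,160 reads, in a single seeded
draw per sample. Samples below the depth are dropped with a warning, never
upsampled. Taxa that become all-zero are retained so the rDNA/rRNA taxon
axes stay aligned. An averaging mode over multiple draws is intentionally
not provided; downstream statistics operate on one rarefied realisation with
a recorded seed.

## Diversity conventions

* Simpson is the Gini-Simpson form 1 − Σp²; the inverse form is behind a
  flag, as naming conventions differ between software ecosystems.
* Chao1 is bias-corrected, `S + F1(F1−1)/(2(F2+1))`; the classic variant is
  behind a flag and falls back to the corrected form when F2 = 0.
* PCoA performs classical metric scaling on the double-centred squared
  distance matrix. Negative eigenvalues (non-Euclidean input) are reported,
  never silently zeroed; axis proportions are computed over the positive
  eigenvalues only. A Lingoes correction is available behind a flag but off
  by default.

## Activity regression and environmental attribution

The abundance-activity regression pools all records of a group (e.g. host
vs non-host communities) across dates and conditions and fits OLS of
log10(ratio) on log10(rDNA abundance). Base 10 throughout; the base rescales
slope and intercept but not R². Pooling matches the single-cloud fit used in
this kind of analysis; per-condition fits are a thin wrapper away (filter
records by condition).

Residuals from that fit are attributed to environmental factors in two ways:

1. **Per-factor regression.** Residuals are first averaged per sampling
   event (date × condition). Environmental factors only vary at event
   resolution, and all records within one sample share a compositional
   normalizer, so per-record regression would treat thousands of records as
   independent replicates of a sample-level signal and grossly overstate
   significance. Factors are z-scored so slopes are comparable across units.
2. **Permutation importance.** A random-forest regressor is fitted to the
   event-level mean residuals and each factor's importance is the mean
   decrease in R² over repeated within-column shuffles
   (`sklearn.inspection.permutation_importance`, 30 repeats by default,
   fixed seed). The reported p-value per factor is a one-sided t test of the
   repeated importances against zero; ranks 1..n are always returned.

A structural point worth knowing: because sequencing proportions are
renormalized per sample, an activity effect shared by *every* taxon in a
sample cancels against the normalizer and is unidentifiable. Environmental
effects are therefore detectable only insofar as a group of taxa responds
differently from the abundance-weighted community mean — in a host-dominated
aggregate, the phycospheric (non-host) community's response is measured
against a normalizer pinned by the host. The synthetic generator encodes
exactly this structure (below).

Order-level activity profiles collapse each order within a sample pair to
the **ratio of summed proportions** (default) rather than the mean of
per-ASV ratios: summed proportions weight members by abundance and are
robust to noisy ratios of rare ASVs. The mean-of-ratios alternative is a
flag.

## Association tests

All permutation tests use the add-one rule p = (1 + #extreme)/(n_perm + 1),
default 999 permutations, seeded `numpy` Generators.

* **Mantel**: Pearson (default) or Spearman correlation of lower-triangle
  vectors, rows/columns of the second matrix permuted jointly. One-sided
  ("greater") by default, matching the usual question of positive covariance
  of community turnover.
* **MRPP**: observed δ = Σ (n_g/N) · mean within-group distance; the
  chance-corrected effect size A = 1 − δ/E[δ] uses the permutation mean as
  E[δ]. With strata, labels permute only within each stratum — a sample can
  never change stratum, which the test suite asserts structurally.
* **Paired Wilcoxon**: two-sided signed-rank test; zero differences are
  discarded (simple and conventional); if all differences are zero the
  result is p = 1 with statistic 0, since the data carry no evidence of a
  shift. Incomplete pairs are dropped and counted.
* **Spearman panels** report raw p (t approximation) and Benjamini-Hochberg
  adjusted p across the whole panel; constant features yield missing values
  rather than a coefficient.

## βMNTD, βNTI, and the null model

βMNTD is abundance-weighted: each taxon present in one community contributes
its relative abundance times the patristic distance to its nearest taxon in
the *other* community (shared taxa contribute zero), averaged over both
directions. The null model shuffles taxon labels across all tips of the
phylogeny pruned to the taxa observed in the analysed table — equivalently,
it permutes rows/columns of the patristic matrix — which preserves each
community's abundance multiset and richness while randomizing phylogenetic
positions. βNTI is the z-score of the observed βMNTD against 999 such
shuffles; |βNTI| ≤ 2 is read as stochastic assembly, βNTI < −2 as
homogeneous selection, βNTI > 2 as heterogeneous selection (the classifier
is total even though strongly filtered systems rarely produce the positive
tail). A degenerate null (sd = 0) yields a missing βNTI with a diagnostic
rather than a value.

An optional taxon-exclusion filter removes (for example) host cyanobacterial
ASVs and renormalizes before the analysis, for assembly questions about the
phycospheric community alone.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses assume.

**Paired dataset.** A Yule tree (pure-birth, exponential waiting times,
ultrametric) over `n_taxa` (default 300) tips. A host clade — the subtree
closest to 10% of taxa — receives a fixed share of abundance mass (default
0.75, the typical dominance of the bloom-former in aggregate material).
Log abundances are lognormal (`rank_sdlog` 1.5) with smooth date-driven
turnover (per-taxon sinusoidal loadings, `turnover_sd` 1.0) over `n_dates`
(default 17, fortnightly May-November dates) × three conditions. The latent
activity of taxon i in sample s is

    L_is = α + β·log10(a_is) + Σ_f γ_f·z_fs·[i not in host clade] + ε_is

with defaults β = −0.6, σ = 0.3 — calibration choices producing a fitted R²
near two thirds, not published estimates, since the source analyses print
R² but not slopes. Environmental factors are generated on natural
measurement scales (seasonal sinusoids + noise + condition offsets; DIN is
the sum of the nitrogen species, giving realistic collinearity) and enter
the model through their z-scores. The environmental term applies to
non-host taxa only: as explained above, a community-wide effect would cancel
in the compositional renormalization, whereas a phycosphere-specific
response measured against the host-pinned normalizer is identifiable — and
it reproduces the qualitative host result that host residuals show no
environmental signal. Both libraries are multinomial at the configured
depth, so zero inflation arises from finite sampling alone.

**Assembly scenarios.** The *selection* scenario emulates consistent habitat
filtering as the limiting case of a perfectly conserved niche trait:
community membership is drawn mostly (1 − 2·`selection_strength` of picks)
from one phylogenetically isolated clade — the clade of 20-40% of taxa
maximizing the ratio of cross-clade to within-clade patristic distance —
plus a uniform immigration stream whose members carry a strong abundance
handicap (`selection_strength²/40`), so immigrants seed the regional pool
without carrying abundance mass. During development, a 1-D Brownian trait
filter (an obvious alternative) proved too weakly phylogenetically conserved
on trees of this size to concentrate communities in any clade, which is why
the filter acts on clade membership directly. The *neutral* scenario samples
taxa uniformly — exactly the null model's own mechanism — and is the
calibration standard: its βNTI values are approximately standard normal.
Within-community abundances in scenarios use a flatter lognormal
(`community_evenness_sdlog` 0.3): the βNTI signal scales with the effective
number of non-shared taxa, and extreme dominance would starve the statistic
of information in small simulated communities, unlike the thousands-of-ASV
tables of real studies.

**What the generator does not emulate:** sequence errors and chimeras, 16S
copy-number variation, time-series autocorrelation beyond smooth seasonal
curves, dispersal limitation (RCbray-style partitioning of the stochastic
fraction is out of scope), and the taxonomic richness of real aggregates.
Passing recovery tests therefore demonstrate the *statistical machinery* is
correct and calibrated under the stated model, not that real communities
satisfy the model.

## Numerical conventions and degenerate inputs

* Seeds: every stochastic component draws from `numpy.random.Generator`
  seeded via `SeedSequence` spawning, so all artifacts are pure functions of
  their configuration; identical seeds reproduce byte-identical outputs.
* Rarefaction below depth drops the sample (warning); depth equal to the
  total returns the sample unchanged.
* OLS with a constant response returns slope 0, R² 0 and a
  `constant_response` flag; zero variance in the predictor is an error.
* Mantel with a zero-variance distance vector is an error; MRPP strata that
  all contain a single group are an error (a single such stratum only
  warns, contributing no permutation freedom).
* Problem sizes in the validation suite (community counts, permutation
  counts, simulation replicates) are chosen so each property is measured at
  Monte-Carlo precision comfortably inside its tolerance; the acceptance
  script states each size in its `n` field.

## Known limitations

* βNTI power depends on community overlap: near-identical communities give
  the null nothing to contrast (shared taxa contribute zero under any
  relabelling), so βNTI is conservative for extremely homogenised tables.
* The permutation-importance p-values are heuristic (t test over shuffle
  repeats), intended for ranking rather than formal inference; the
  per-factor regression p is the inferential quantity.
* BIOM support covers the HDF5 2.1 sparse layout (ids + matrix groups);
  observation/sample metadata embedded in BIOM files are ignored — metadata
  travel in the dedicated TSV.
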