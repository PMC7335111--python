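# Methods

This note documents the models, rules and numerical choices behind
`glioproteo`, and what the synthetic data used by the test suite does
and does not establish about real data.

## Quantification model

Reporter intensities from isobaric (TMT) multiplex sets are referenced
to a pooled global internal standard (GIS) channel carried in every
set: for feature *f* in sample *s* belonging to set *t*,

    x_fs = log2( I_fs / GIS_ft ).

Ratios from different sets, and from the two GIS batches, are made
comparable by two sequential median centerings: each sample's median
over features is subtracted, then, within each GIS batch, each
feature's median over that batch's samples.  After the second step the
within-batch feature medians are exactly zero.  The composite is *not*
idempotent: the batch-centering step is a fixed point, but the output
generally has nonzero sample medians again (of order noise/√n_features),
so a second full pass moves values slightly — the operation is a
contraction toward the median-polish fixed point, not a projection.
(Counterexample: one batch with samples s1, s2 and features
f1 = (1, −1), f2 = (−1, 1), f3 = (2, −2): all within-batch feature
medians are zero, yet the sample medians are ±1.)

Missing measurements are carried as an explicit mask.  Where a
complete matrix is required, missing entries in a feature row are
replaced by the row's second-smallest observed value (the second order
statistic; duplicated minima mean the imputed value can equal the
minimum).  The per-feature reading is the default because a global
second-smallest value is on an arbitrary scale relative to most
features; a `scope="global"` flag provides the alternative.  Coverage
filtering keeps features observed in at least `min_gis` GIS batches
(all batches for global proteome data; three is the phospho
convention).

### Phospho-site aggregation

Phosphopeptides covering a site are first averaged (arithmetically, on
the raw ratio scale) within each phosphorylation class — mono-, di-,
tri-or-more — and the class values I_s1, I_s2, I_s3 are combined by
the self-weighted mean

    I_s = Σ_n I_sn² / Σ_n I_sn ,

which up-weights the class carrying more signal.  Absent and
zero-intensity classes are excluded from both sums (avoiding 0/0); a
site/sample with no contributing class stays missing.  The statistic
is scale-equivariant (λ·I_sn ⇒ λ·I_s), bounded by the smallest and
largest class values, and never below the arithmetic mean of the
present classes.  Values are then log2 transformed.

## Subtype discovery

Samples are clustered by complete-linkage agglomeration on
d = 1 − Pearson r (computed over shared observed features).  Consensus
clustering draws 80% of the samples without replacement for each of
1000 iterations, clusters the subsample, and cuts the tree at each K
in 2..6; the consensus entry for a sample pair is its co-clustering
count over its co-sampling count (pairs never co-sampled stay
undefined and are excluded downstream).  The proportion of ambiguous
clustering, PAC(K), is the fraction of defined off-diagonal consensus
values strictly inside (0.1, 0.9); the selected K minimizes PAC, ties
going to the smaller K (parsimony).  Final labels cut a
complete-linkage tree of 1 − consensus at the selected K.

Key proteins are taken from a PCA of the (complete) matrix: the top
10% of features by absolute PC1 loading, floor-rounded, ties broken by
feature id so the selection is deterministic (3909 features ⇒ 390).

Cluster–phenotype association uses a permutation test whose statistic
is within-phenotype pair purity — among sample pairs sharing a
phenotype, the fraction that also share a cluster — with the phenotype
labels permuted and p = (1 + #{perm ≥ obs}) / (n_perm + 1).  Note the
permutation p-value is discrete and conservative (P(p ≤ t) ≤ t), and
with few samples distinct permutations can reproduce the observed
partition, so "perfect association" does not always reach the
1/(n_perm+1) floor.

## Differential expression

Per-feature two-sided unpaired Student's t-tests (equal variance;
Welch behind a flag) with Benjamini–Hochberg FDR.  A Shapiro–Wilk
screen reports, per group, the fraction of features rejecting
normality at 0.05; it is advisory and never gates the t-tests.
Differential phospho hits whose parent protein is itself differential
(p < 0.05) in the same direction are filtered out, leaving phospho
signals not explained by protein abundance.  RNA–protein agreement is
summarized by per-gene Spearman correlations over shared samples
(minimum three), with the fraction of significantly positive genes at
FDR < 5% reported.

## Enrichment

Over-representation uses the upper-tail hypergeometric test of a query
list against each gene set restricted to the declared background,
after set-level filters (size 5–150, exact-duplicate membership
removal) and a minimum of four query hits per tested set; BH FDR is
computed over tested sets.  Set–set similarity edges use the overlap
coefficient |A∩B| / min(|A|,|B|) at a 0.5 cutoff.

ssGSEA walks each sample's genes from highest to lowest expression.
In-set genes advance a weighted CDF with weight rank^0.75 (ranks from
the sample's own expression; the score therefore depends on the data
only through ranks and is invariant under any strictly monotone
transform); out-of-set genes advance a uniform CDF; the enrichment
score is the sum of the CDF difference over the whole walk (the
integrated running sum).  Raw scores are reported; a `normalize` flag
divides by the global score range.  Note that with any weight exponent
above zero the statistic has a strictly positive expectation under
random gene memberships (the weighted CDF rises earlier in the walk on
average), so only the unweighted (exponent 0) variant is exactly
zero-mean under gene-label permutation; the test suite pins the
exponent-0 calibration and documents the weighted offset.  RNA
subtypes are assigned per sample as the argmax score over the four
subtype signatures, ties broken by a fixed signature order and
flagged.

## Surrogate subtype (sGPC) classification

Signatures are equal-sized disjoint GPC1-high/GPC2-high gene lists
selected by t-test (top-n per side, or all genes under an FDR cut with
the two sides truncated to equal length).  For single-cell use, the
candidate pool is first restricted to the 1000 highest-expressed genes
of the bulk training cohort that are detected in at least half of the
cells.  Expression is z-scored per gene across the cells/samples being
classified (per-cell z-scoring available behind a flag).

For a z-vector Z the score is ΔZ = mean(Z over GPC1-high) − mean(Z
over GPC2-high); the null permutes which signature genes belong to
which side (sizes preserved) and the two-sided p-value is
(1 + #{|ΔZ_perm| ≥ |ΔZ_obs|}) / (n_perm + 1), bounded below by
1/(n_perm+1) by the +1 smoothing.  A cell is called GPC1 (ΔZ > 0) or
GPC2 (ΔZ < 0) only at p < 0.05 with 1000 permutations; otherwise it
stays unassigned.  The vectorized screen gives every cell its own
independent permutation family (a uniform random size-m subset per
permutation, drawn by arg-partitioning i.i.d. uniforms), so cells are
mutually independent under the null and the fraction of null cells
called concentrates at the binomial rate around
⌊α(n_perm+1)⌋/(n_perm+1) ≈ 0.049.

Bulk cohorts without proteome data are classified by a random forest
(300 trees, `max_features` tuned by 5-fold cross-validated grid
search, fixed seed) trained on the top-100 differential genes after
the training and test cohorts are merged and quantile-normalized
(every sample mapped onto the mean-of-order-statistics reference;
ties keep input order, so sorted columns agree exactly).  Calls are
emitted only when the winning class probability reaches 0.60.

## Dose–response processing

Viability points are smoothed per (drug, concentration) stratum across
cell lines: a point is removed only when it exceeds **both** 1.5 and
Q3 + 3·IQR (linear-interpolation quantiles) of its stratum — targeted
agents are not expected to boost proliferation, so such points are
artifacts.  Strata with fewer than four points skip the quantile rule
(kept, flagged).  Drug–cell pairs with no retained point at any
concentration are dropped.

AUC is the trapezoid rule of viability against log10 dose, divided by
the log10 dose range, so a flat fully-viable curve scores exactly 1
and lower values mean higher sensitivity.  The dose–response model is
the four-parameter log-logistic

    f(x) = c + (d − c) / (1 + exp(b·(ln x − ln e))),

fitted by bounded least squares (0 ≤ c, d ≤ 1.5) from a 3×2 multi-start
grid (inflection initialized at the 15/50/85% log-dose quantiles,
slope at 0.5 and 2) taking the lowest residual.  The assigned ED50 is
min(e, top tested dose) — 20 μM for the screen grid — and a failed fit
is assigned the top dose with a status flag.

Precision caveat: on the screen's 7-point 4-fold dilution grid with
viability noise sd 0.05 and unit slope, the Fisher information of the
design bounds sd(ln ED50) at about 0.26, i.e. a median relative error
around 17% for any estimator; the fitted ED50's statistical
uncertainty at this design is therefore of that order, and tighter
recovery requires steeper slopes, replicate wells or denser grids.

Subtype selectivity is a per-drug two-sided two-sample
Kolmogorov–Smirnov test on AUC (and assigned ED50) between subtype
groups (minimum three cells per group), the sensitive subtype being
the one with the lower mean.  Drug–biomarker association is Spearman
correlation between tissue feature abundance and per-cell response
summaries (minimum five shared cells), BH-corrected per metric.

## Variant-peptide database

Transcripts with FPKM > 1 contribute.  Each SNV/indel is applied
independently to the coding sequence and translated.  A variant whose
translation stops before the original terminal codon is a stop gain
and is skipped entirely (a truncated peptide is indistinguishable from
one ending at a missed-cleavage limit).  A variant destroying the stop
codon triggers read-through into the downstream sequence for at most
20 extra residues, each requiring read depth above 3 at all three
codon positions, stopping early at a new stop codon.

Digestion is tryptic (cleave after K/R, not before P).  Only peptides
spanning a variant residue are emitted, with at most three missed
cleavages on each side of the variant span — five on the N-terminal
side for stop-loss products, which protects short read-through tails —
and a minimum length of eight residues.  The database is deduplicated
at the peptide level with deterministic ordering.  Sample coherence
between genomic and proteomic variant calls uses the Jaccard
coefficient; 1 − J is the mutation distance (distance 1 by convention
when both sets are empty, flagged as undefined).

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical shapes the pipeline assumes:

- **Proteome cohort** — 39 samples in two latent subtypes (26/13),
  1000 proteins, two GIS batches, Gaussian log2-ratio noise (sd 0.5),
  20% informative proteins shifted by 1.0 log2 unit between group
  means (half up in each subtype), 5% missingness completely at
  random.  The shape mirrors a single-center IDH wild-type GBM cohort
  so subtype-number recovery runs at realistic size.
- **Phosphopeptides** — sites with one to three phosphorylation
  classes, one or two peptides per class, lognormal base intensities;
  the planted class means define the ground-truth site value.
- **Single cells** — i.i.d. standard-normal z-scores over the
  signature genes (the calibration null), optionally shifting each
  labeled cell's own signature side upward.
- **Drug screen** — 60 drugs × 50 cells on the 7-point 4-fold dilution
  grid topping at 20 μM, 4PL truth with slope U(0.5, 2), floor
  U(0, 0.2), ceiling U(0.9, 1.1), log-uniform inflection, noise
  sd 0.05; injected outliers are placed above both removal thresholds
  of their contaminated stratum (capped below a quarter of the stratum
  so the quantiles stay clean) to make the smoothing rule verifiable.
- **Variant fixture** — four toy transcripts covering a missense SNV,
  an in-frame deletion, a stop-gain, and a stop-loss whose downstream
  depth supports exactly five read-through codons.

None of this emulates peptide-level identification error, batch
effects beyond GIS structure, dropout patterns of real single-cell
data, non-Gaussian viability noise, or correlated missingness — so
green tests certify the stated rules and their calibration under the
assumed noise models, not performance on real cohorts.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); the pipeline fans a single global seed
out to per-stage seeds via a stable hash, so stages are independently
reproducible and rerunning a configuration reproduces artifacts
bit-identically.  The test suite runs consensus clustering at 150
resamples for the five-seed recovery property and 1000 resamples for
the cohort-scale selection check; the null-calibration check uses
2000 cells × 1000 permutations; dose–response recovery suites use 100
curves.  Permutation p-values are never zero by construction.

## Known limitations

- Equal-variance t-tests are sensitive to strong heteroscedasticity;
  the Welch flag exists but is not the default.
- The consensus loop subsamples samples only (no feature resampling),
  matching the common default of consensus-clustering software.
- The bulk classifier contract is "any probabilistic classifier behind
  a fixed interface"; the random-forest grid is small by design and
  not a tuned model.
- Fusion-gene translation and contaminant databases are out of scope
  for the variant database; only SNVs and small indels are handled.
- ED50 values near or above the top tested dose are reported at the
  cap and should be treated as censored, not estimated.
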