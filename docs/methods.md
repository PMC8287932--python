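# Methods

## APOBEC-signature mutation counting

An APOBEC mutation is a somatic single-nucleotide substitution C→T or C→G
whose mutated cytosine lies in a TCW trinucleotide context (W ∈ {A, T}).
Classification canonicalizes every record to a pyrimidine center: when the
reference base is A or G the plus-strand triplet and the ALT allele are
reverse-complemented before testing, so a plus-strand G→A at [A|T]GA counts
as a minus-strand C→T at TCW. This both-strand convention is universal in
mutational-signature work; the literal plus-strand-only reading is kept
behind a `plus_strand_only` flag purely for sensitivity analysis. W is
strictly {A, T}: TCC and TCG contexts never qualify, even though some of
the literature uses the looser TCN.

Records whose context cannot be read — an N in the triplet or the ALT, or a
position at a contig edge — are flagged non-classifiable and excluded from
classification but reported in the QC summary, never silently dropped.
Duplicate records (same sample/chrom/pos/alt) are kept and counted twice
with a logged warning: no deduplication rule is part of the method, and
keeping is the conservative reading of "the number of mutations". Sex
chromosomes and mitochondria are not filtered. For VCF input only PASS or
unfiltered rows are accepted by default (overridable); multi-allelic rows
split into one record per ALT; indels and MNVs are skipped with a count.

Two independent implementations exist: a per-record string path
(`classify`, built on `context_of`) and a vectorized integer-coded path
(`classify_catalog`) used for cohort-scale counting. They are
cross-checked against each other and against a brute-force two-strand
oracle in the test suite.

The per-sample display value is `log10(n_apobec + 0.5)`. The alternative
reading "log10(count) + 0.5" cannot represent zero-count tumors, which is
the transform's stated purpose, so the shift goes inside the logarithm.
Being strictly monotone, the transform provably leaves every rank
correlation unchanged, and the tests assert this to machine precision.

The 96-channel context matrix (6 pyrimidine substitutions × 16 flank
combinations, substitution-major, flanks alphabetical) is a QC aid: row
sums must equal each sample's classifiable count and the four TCW channels
(T[C>T]A, T[C>T]T, T[C>G]A, T[C>G]T) must sum to its APOBEC count.

Counts are reported as-is, with no normalization for exome versus
whole-genome territory and no hypermutator exclusion or coverage filter:
the method operates on whatever call set it is given.

## Signature scoring

A signature score is the arithmetic mean of the signature genes found in
the matrix, per sample; a z-score variant (mean of per-gene standardized
values, constant genes contributing zero) is available. Gene matching is
case-insensitive exact symbol match with no alias resolution — symbol
harmonization is the user's responsibility. Missing values are skipped in
the per-sample mean; a sample missing every signature gene receives a
missing score and is dropped from joins with a log line. No expression
normalization or log transform is applied by default (matrices are assumed
already processed); a `log2` option applies log2(x + 1) before averaging
for linear-scale matrices.

The six-gene hypoxia-inducible p53 response set (BTG2, CYFIP2, INPP5D,
KANK3, PHLDA3, SULF2) is built in. The 51-gene hypoxia metagene is shipped
as an editable plain-text gene-set file rather than hard-coded: its exact
symbol spellings depend on the annotation vintage of the user's matrix, and
nothing in the package logic depends on them.

## Correlation analysis

Spearman's rho is computed as the Pearson correlation of average ranks
(scipy's `rankdata` supplies the ranks; the rho and P value are computed
here and cross-checked against `scipy.stats.spearmanr` in the tests).
Two-sided P values use the t approximation with n − 2 degrees of freedom
for n ≥ 10 and exact enumeration of all n! pairings (conditioning on the
observed tie pattern) below that; |rho| = 1 under the t path reports P = 0.
Missing data are handled pairwise-complete with the per-pair n reported.
Constant vectors and fewer than three complete pairs are errors, not NaNs.

Cohorts are retained only when strictly more than `min_n` (default 100)
samples carry mutation data. P values are two-sided throughout — the more
conservative choice where sidedness is unstated — with significance at
α = 0.05. No multiple-testing adjustment is applied by default; an optional
Benjamini–Hochberg column is clearly labelled as an extra. Per-gene
expression columns are correlated untransformed, since the rank statistic
makes monotone transforms irrelevant.

## Bench-assay quantification

* **Foci thresholds.** A cell is 53BP1-positive iff it has strictly more
  than 5 foci, RPA-positive iff strictly more than 6 — the inequalities are
  strict exactly as specified, and the boundary cases (5 vs 6, 6 vs 7) are
  pinned in tests. Conditions counted at fewer than 150 cells warn.
* **Replication catastrophe** is the co-occurrence readout: the percentage
  of cells positive on both channels, which can never exceed either
  single-channel percentage (asserted as a property).
* **Nuclear area.** Groups (by default double-positive vs not) are
  compared by a two-sided *unpaired* Welch t test. The global convention
  elsewhere in the analysis is a paired t test for two means, but per-cell
  areas across damage groups are unpaired observations with unequal group
  sizes, so pairing is not applicable; this deviation is deliberate.
  More than two groups use one-way ANOVA.
* **ΔΔCt.** Per biological replicate, ΔCt = Ct(target) − Ct(control gene,
  default 18S) within a condition; ΔΔCt subtracts the same replicate's
  reference-condition ΔCt; fold = 2^(−ΔΔCt). Folds are averaged over
  replicates with SEM, so the reference condition's fold is exactly 1 in
  every replicate, and any per-block Ct offset cancels.
* **Deamination gels.** The primary metric is the mean product-band
  intensity per condition relative to the reference condition's mean
  product intensity (reference ≡ 1); the per-lane product fraction
  P/(S + P) is a secondary QC metric only.
* **TCW site scanning** locates T-C-[A|T] motifs (optionally on both
  strands) and verifies that the bundled deamination substrate oligo
  carries exactly one plus-strand site, the TCA following its internal N.

## Synthetic cohort generator

The generator emulates a tumor cohort in which hypoxia causally drives
APOBEC mutagenesis. Per sample *i*: latent hypoxia `h_i ~ N(0, 1)`; total
mutation count negative-binomial with mean λ (default 100) and dispersion
k (default 2) — overdispersion being the norm for tumor burdens, with
Poisson recovered as k → ∞ — floored at 1 so every sample appears in its
catalog; APOBEC count binomial(total, f_i) with
`f_i = logistic(a + b·h_i)` (defaults a = −1, b = 1, putting the typical
APOBEC fraction near 0.27). APOBEC events are placed uniformly at distinct
TCW sites of a simulated i.i.d. genome (default 100 kb, GC 0.45, which
carries ≈ 7000 TCW sites; generation refuses genomes with fewer than 10×λ
sites), drawing plus- or minus-strand sites and emitting the correct
plus-strand REF/ALT by complementation, with C→T chosen over C→G at 0.7
(the approximate empirical split of APOBEC signatures). Background events
land at uniform interior positions with a uniform non-reference ALT, one
substitution per site per sample.

A background event may coincidentally be TCW-APOBEC; truth labels record
intent. With `exclude_collisions=True` such placements are rejected, so
counted and injected APOBEC mutations must agree exactly — exactness where
tested, realism where simulated.

Expression: gene g, sample i gets `μ + β_g h_i + ε`, ε ~ N(0, σ²), with
β = 1 on the 51 hypoxia-signature genes, β = 0.5 on the six p53 genes
(hypoxia-responsive but more weakly in this model) and β = 0 on 100 filler
genes; μ = 8 and σ = 1 on a log2-like scale. Everything is deterministic
given parameters and seed, to the byte in the written files.

What the generator does **not** emulate: chromatin- and replication-timing
mutation-rate heterogeneity, signature mixtures beyond a single APOBEC
process, oxygen-cycling kinetics (hypoxia enters only as a static latent
covariate), copy number, purity, or batch structure in expression. Passing
tests therefore demonstrate correctness of the counting, scoring and
correlation machinery under the stated generative model — not that real
cohorts will show any particular effect size.

## Problem sizes and calibration checks

The simulation-based checks use cohorts sharing one 100 kb genome:
type-I calibration runs 1000 zero-coupling cohorts of n = 150 and expects a
rejection rate within 0.05 ± 0.02 at α = 0.05; the power check runs 200
cohorts at (b = 1, a = −1, n = 200, λ = 100) and expects ≥ 95% positive
significant correlations; median rho is checked to increase over
b ∈ {0, 0.5, 1, 2} (200 replicates at b = 1, 60 at the other slopes).
These sizes make the full suite run in about a minute on one CPU while
keeping the binomial standard error of the type-I estimate (≈ 0.007) well
inside the acceptance band.

## Known limitations

* Gene-symbol matching is exact; users with mixed annotation vintages must
  harmonize symbols first.
* The exact Spearman P value enumerates n! pairings and is therefore
  limited to n ≤ 9; at n = 10 the t approximation takes over, which is
  slightly anti-conservative in the extreme tails.
* VCF sample identity is taken from a single-sample column, a `SAMPLE`
  INFO field, or a per-file override; multi-sample VCFs with genotype
  columns are not demultiplexed.
* The pipeline treats one input as one cohort; multi-cohort comparisons
  are composed by the user from `filter_cohorts` and repeated runs.
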