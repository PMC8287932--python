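# tcwsig

Tools for linking tumor hypoxia to APOBEC mutagenesis in cohort data:
per-sample counting of APOBEC-signature somatic mutations, gene-signature
summary scoring of tumor expression matrices, and Spearman rank-correlation
analysis between the two — plus the quantification rules of the
accompanying bench assays (immunofluorescence foci thresholds, nuclear-area
comparison, ΔΔCt qPCR, deamination-gel quantification) and a synthetic
cohort generator with ground-truth labels.

## Who it is for

Cancer genomics analysts who have per-sample somatic SNV calls (VCF or a
MAF-like TSV), a reference genome (FASTA) and a gene-by-sample expression
matrix, and want to ask whether APOBEC mutation burden tracks a hypoxia
expression signature across a cohort; and bench scientists who want the
matching assay quantification done reproducibly from tidy tables.

## The statistics at the core

**APOBEC mutation.** A somatic C→T or C→G substitution whose mutated
cytosine lies in a TCW trinucleotide context, W ∈ {A, T}. Counting is
strand-symmetric via pyrimidine canonicalization: a G→A/G→C on the plus
strand whose reverse-complement context reads T-C-W is the same deamination
event observed from the other strand (a `--plus-strand-only` flag exists
for sensitivity analysis). W is strictly {A, T}; TCC/TCG never qualify.

**Per-sample burden.** For sample *i*, `n_apobec_i` is the number of such
mutations, displayed as `log10(n_apobec_i + 0.5)` so zero-count tumors stay
finite. Because the shift-then-log transform is strictly monotone, it
changes no rank correlation — a property the test suite verifies exactly.

**Signature score.** For a gene set *S* (the bundled 51-gene hypoxia
metagene `hypsig`, the built-in 6-gene p53 response set `p53genes`, or any
user file), the per-sample score is the mean expression of the genes of *S*
present in the matrix (optionally the mean of per-gene z-scores).

**Correlation.** Spearman's rho — Pearson correlation of average ranks —
with two-sided P values (t approximation for n ≥ 10, exact enumeration of
all pairings below that). Cohorts enter the analysis only when they have
strictly more than 100 samples with mutation data.

**Synthetic cohorts.** A latent hypoxia level `h_i ~ N(0,1)` drives both
signature-gene expression (`x_gij = μ + β h_i + ε`) and the APOBEC fraction
of each tumor's mutations (`f_i = logistic(a + b·h_i)`); total burdens are
negative-binomial, and APOBEC events are injected at real TCW sites of a
simulated genome on either strand. Ground truth is recorded for exact
recovery tests.

## Worked example

```python
import tcwsig as t

params = t.CohortParams(n_samples=150, seed=42)     # defaults: a=-1, b=1
cohort = t.simulate_cohort(params, outdir="demo")   # FASTA/TSV/VCF + truth

counts = t.count_per_sample(cohort.genome, cohort.catalog)
print(counts.head(3).to_string(index=False))

scores = t.score_signature(cohort.expression, t.hypoxia_signature()).scores
table = t.build_score_table({"hypsig": scores}, counts)
print(t.spearman(table["hypsig"], table["n_apobec"], "hypsig", "n_apobec"))
```

prints

```
sample  n_total  n_classifiable  n_apobec  log_shifted
 S0001      202             202        97     1.989005
 S0002       42              42         7     0.875061
 S0003      195             195        78     1.894870
CorrelationResult(x_name='hypsig', y_name='n_apobec', n=150, rho=0.5359262943625327,
                  p_value=1.580883625757762e-12, method='average ranks; t approximation p')
```

Sample S0001 carried 202 somatic SNVs of which 97 are TCW-context C→T/C→G;
across the 150 tumors the hypoxia score and the APOBEC count are strongly
rank-correlated (rho ≈ 0.54), recovering the positive coupling the
generator injected (slope b = 1).

The same analysis end to end from a shell, driven by a YAML config:

```
tcwsig run --config config.yaml          # simulate/load -> count -> score -> correlate
tcwsig count-apobec --genome ref.fa --mutations calls.vcf --out counts.tsv
tcwsig assay --cells cells.tsv --ct ct.tsv --target-gene A3B --out assay.json
```

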