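# mztseq

RNA-seq analysis of the maternal-to-zygotic transition (MZT) with
first-class support for repetitive elements.  Early mouse embryos activate
their own genome at the 1–2-cell stage while degrading maternally deposited
transcripts; much of the newly transcribed material at this stage comes from
repeat elements (LINEs, SINEs, LTR retrotransposons), whose reads map to
hundreds or thousands of genomic copies and are discarded by conventional
unique-mapping pipelines.  `mztseq` is for researchers who need to quantify
genes *and* repeat families from heavily multi-mapped alignments, test for
differential expression in very small designs (n = 2–3 embryo pools per
condition), and ask whether a mutant embryo completed the MZT.

## What it computes

**Multi-mapping-aware counting.**  Every equally best alignment of a read is
kept.  If a read's alignments overlap N distinct gene loci, each locus
receives weight 1/N², so the read contributes total gene mass 1/N.  Repeat
elements are first binned by RepeatMasker repeat name — alignments to many
same-name copies count as one hit to that family — and the same 1/N² rule is
applied across distinct repeat names.  Gene and repeat tallies are
independent.

**Monte-Carlo negative-binomial test.**  For each pair of conditions, counts
are median-of-ratios normalized; features with mean raw count below 10 in
both conditions are not tested.  A per-feature dispersion α is estimated by
the method of moments (Var = μ + αμ²) and floored by a fitted dispersion–mean
trend α(μ) = a₀ + a₁/μ.  The null distribution of the log₂ fold-change is
simulated: each iteration draws NB(μ, α) counts for every sample, averages
them into the two conditions, and records the log₂ ratio.  The observed
fold-change is converted to a z-score against this distribution and to a
two-tailed normal p-value; genes and repeat families are corrected together
with Benjamini–Hochberg, significant at adjusted p < 0.05.

**MZT readouts.**  Tallies of zygotically activated (2C-enriched) and
maternally repressed (oocyte-enriched) genes and repeats; a sample dendrogram
on 1 − Pearson correlation with average linkage; PCA of transcriptomes; the
gene set driving PC1; and the per-gene standardized (mean 0, sd 1) matrix
behind the expression heat map.

**Synthetic ground truth.**  A generator produces the full three-group
design (oocyte, wild-type 2C, mutant 2C) with known activated/repressed
classes and a failed-MZT mutant whose means are the mixture
λ·oocyte + (1−λ)·wt2C, plus multi-mapped hit records with a brute-force
counting oracle — so the whole pipeline is testable without any sequencing
data.

## Worked example

```python
import mztseq as m

truth = m.make_truth(seed=7)                      # 2000 genes + 100 repeat families
matrix = m.simulate_count_matrix(truth, m.SimDesign(seed=7))

records = m.run_differential_expression(matrix, m.OOCYTE, m.WT2C, m.DEConfig(seed=7))
s = m.classify_comparison(records, m.OOCYTE, m.WT2C)
print("genes activated/repressed:", s.genes_up, s.genes_down)
print("repeats activated/repressed:", s.repeats_up, s.repeats_down)

norm = m.normalize_counts(matrix, m.compute_size_factors(matrix))
expr = m.log_transform(norm)
dend = m.hierarchical_cluster_samples(expr)
print("leaf order:", dend.sample_ids)
pca = m.principal_components(expr)
print("PC1 variance fraction: %.3f" % pca.variance_fraction[0])
```

prints

```
genes activated/repressed: 403 399
repeats activated/repressed: 20 20
leaf order: ['wt2C_1', 'wt2C_2', 'wt2C_3', 'mut2C_2', 'mut2C_1', 'mut2C_3', 'oocyte_1', 'oocyte_2', 'oocyte_3']
PC1 variance fraction: 0.812
```

The truth table planted 400 activated and 400 repressed genes (20 + 20
repeats) at ≥ 4-fold, so the test recovers essentially all of them with few
false calls.  In the dendrogram the mutant 2C samples form a clade with the
oocytes rather than with wild-type 2C — the failed-MZT signature (the
simulated mutant retains 80% of the maternal profile, λ = 0.8) — and a
single principal component separating wild-type 2C from the maternal-like
samples carries ~81% of the variance.

The same stages are scriptable from the shell: `mztseq simulate`,
`mztseq index`, `mztseq count`, `mztseq de`, `mztseq compare`,
`mztseq cluster`, `mztseq pca`, `mztseq heatmap`, and `mztseq run
--config pipeline.yaml` for the whole pipeline with provenance sidecars.

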