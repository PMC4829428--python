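# Methods

## Feature model

The unit of quantification is a *feature*: either a **gene locus** (all
transcripts sharing a `gene_id`; its territory is the union of their exon
intervals, merged where they overlap or abut) or a **repeat family** (every
genomic copy carrying one RepeatMasker repeat name, collapsed under a single
feature id).  Grouping repeats by name rather than by locus is what makes
repeat expression measurable at all: an individual L1 or B1 copy is rarely
identifiable from short reads, but the family is.  Coordinates are stored
1-based closed throughout; the UCSC rmsk table dialect (0-based half-open)
is converted on read.  Redundant transcripts are collapsed by exact
(chromosome, strand, exon-chain) identity — near-identical isoforms are
deliberately kept, since fuzzier redundancy rules are heuristic and
annotation-dependent.  A repeat name colliding with a gene id is prefixed
`repeat:` so ids stay unique.  Where a gene's transcripts disagree on
strand, the locus takes the lexicographically first strand so index
construction is insensitive to input order.

## Weighted counting of multi-mapped reads

For one read, let N_gene be the number of distinct gene loci overlapped by
any of its alignments (an alignment counts when it overlaps a feature
interval by at least `min_overlap` of its own length; default 0.5, i.e.
majority overlap) and N_rep the number of distinct repeat *names* overlapped.
Each gene locus receives 1/N_gene², each repeat family 1/N_rep².  Two
consequences follow directly and are asserted as invariants:

* a read's total gene mass is N·(1/N²) = 1/N — unique reads count fully,
  ambiguous reads progressively less, and no read contributes more than one
  count to either table;
* alignments to many same-name copies collapse to a single family
  membership before weighting, so a read entirely inside one L1 family
  still counts as one full hit to L1.

Gene and repeat tallies are computed independently (a read overlapping both
contributes to both with separate Ns); whether a repeat hit should deflate a
gene's N is not decidable from the method's description, and independence is
the reading that preserves both rules exactly.  Counting is unstranded, as
whole-transcriptome amplification protocols for single embryos are not
strand-specific.  Input is either name-collated SAM/BAM (via pysam) or a
plain `read_id / sample_id / feature_id` hit table, which exercises the
statistics without any alignment machinery.

## Differential expression

**Normalization.**  DESeq-style median-of-ratios: the reference is the
per-feature geometric mean over samples (features containing zeros are
excluded from the reference), each sample's size factor is the median of its
ratios to the reference, and factors are rescaled to geometric mean 1.  If
no feature is positive in every sample the per-sample median of nonzero
counts is used instead, with a warning.

**Filter.**  A feature is tested only if its mean raw (weighted) count is at
least `min_raw_count` (default 10) in at least one of the two conditions.
The filter is condition-level rather than per-sample because designs at this
developmental stage have n = 2–3 per condition.

**Dispersion.**  Counts are modelled NB with Var = μ + αμ² (α = 0 is
Poisson).  Per feature, α_obs = max(0, (s² − μ̄)/μ̄²), where s² is the
within-condition pooled sample variance of normalized counts and μ̄ the
pooled mean.  With 4 residual degrees of freedom α_obs is extremely noisy,
so a trend α(μ) = a₀ + a₁/μ is fitted across features by non-negative least
squares and used as a per-feature **floor**: α_eff = max(α_obs, α(μ)).  The
fit uses all features with μ > 0, including those whose moment estimate
clamps to zero — dropping them would bias the trend upward.  The floor makes
the test deliberately conservative: a feature is never treated as less
variable than its expression level implies.  `DEConfig.constant_dispersion`
bypasses the fit for matrices too small to support it (fewer than 20
features with positive α_obs).

**Monte-Carlo null.**  The null hypothesis is zero fold-change, i.e. a
common mean, so both conditions are simulated from the pooled mean μ̄ of all
samples in the pair.  Each of `iterations` (default 1000) iterations draws
n_a + n_b NB(μ̄, α_eff) counts, averages them into the two conditions and
records log₂((avg_b + c)/(avg_a + c)) with pseudocount c = 1 — the same
transform applied to the observed condition means, keeping observed and null
statistics on one scale.  The simulated distribution is very close to
normal, so z = (obs − sim_mean)/sim_sd is translated to a two-tailed p-value
from the standard normal rather than from the empirical tail; this is what
lets p-values resolve below 1/iterations.  Genes and repeat families enter a
single Benjamini–Hochberg correction (statsmodels' step-up), significant at
adjusted p < 0.05.

**Reproducibility.**  Each feature's null uses its own generator seeded by
(root seed, feature row position), so results are bit-reproducible and
independent of iteration order.  Because the same draws serve both
orientations of a comparison, swapping the conditions negates log₂FC exactly
and changes z only by 2·sim_mean/sim_sd — the Monte-Carlo error of the null
mean, O(1/√iterations).

**Calibration.**  Fed true (μ, α), the z/p machinery rejects at 4.98% at
nominal 5% (measured over 4000 features).  Through the full estimation
pipeline at the default study conditions the observed type-I rate is ≈ 3.8%:
the dispersion floor trades a little power for robustness, exactly as
intended, and false-discovery control at BH 0.05 holds with room to spare.

## Downstream readouts

*Classification*: significant features split by sign of log₂FC into
zygotically activated (enriched in 2C) and maternally repressed (enriched in
oocyte), tallied separately for genes and repeats.  *Clustering*: samples on
1 − Pearson correlation across log₂(normalized + 1) expression, average
linkage (scipy); columns are sorted by sample id before linkage so leaf
order and tie-breaks are deterministic — for mutually equidistant samples
the lexicographically first pair merges first.  The dendrogram exports to
newick with branch lengths as merge-height differences, and cophenetic
distances quantify claims like "mutant 2C is closer to oocyte than to
wild-type 2C".  *PCA*: samples as observations on per-feature-centered,
unscaled log expression (scikit-learn, full SVD); per-gene scaling is left
to the heat map, which standardizes separately.  Sign convention: the
feature with the largest |loading| on each component loads positively.
*PC1 gene set*: features with |PC1 loading| > k·sd(all PC1 loadings),
default k = 2 — a deterministic, testable stand-in for "significantly
associated with PC1", which has no canonical test.  *Heat map*: each
selected row standardized to mean 0, sample sd 1 (denominator n − 1);
zero-variance rows dropped with a warning; rows ordered by average-linkage
clustering of the standardized rows (Euclidean distance, which on
standardized rows is monotone in correlation distance).

## Synthetic ground truth

The generator emulates the statistical structure the analysis assumes, not
any particular dataset: NB counts with dispersion following the declining
trend α(μ) = a₀ + a₁/μ; three conditions (oocyte, wild-type 2C, mutant 2C);
activated and repressed classes with log₂ fold changes log2-uniform over a
fold range, signed by class; and a failed-MZT mutant whose condition means
are λ·oocyte + (1 − λ)·wt2C.  λ = 1 reproduces the oocyte exactly, λ = 0 a
normal 2C embryo; as λ grows, the mutant's cophenetic distance to the
oocytes falls monotonically while its distance to wild-type 2C rises.

Default scenario (chosen once, as realistic desk-scale study conditions):
2000 genes + 100 repeat families; 20% activated and 20% repressed at 4–16
fold; baseline means log-uniform over 20–2000 (spanning the filter boundary
through well-measured features); trend (a₀, a₁) = (0.05, 2.0), i.e.
biological CV ≈ 22% for highly expressed features and ≈ 39% at μ = 20; n = 3
samples per condition; λ = 0.8; equal library sizes unless multipliers are
given.  Class allocation is deterministic (exactly round(frac·n) features
per class and kind); only means and fold sizes are drawn, so a seed fully
reproduces a table.  NB sampling goes through the same
(mean, dispersion) → (n, p) conversion the tester uses, so simulator and
test cannot drift apart in parameterization.

The hit simulator draws, per read, a multiplicity N from a configurable
profile (default 70% unique, 15% N=2, 10% N=3, 5% N=5) and N distinct
features uniformly, and accumulates an oracle count matrix by direct
per-read enumeration of the weighting rules, written independently of the
streaming counter; the two agree bit for bit because they accumulate the
same IEEE-754 additions in the same order.

What the generator does **not** emulate: positional effects (reads are
simulated at the feature level, not as sequences), alignment error,
GC/length bias, sample-specific dispersion, correlated features, or
zero-inflation beyond what NB sampling produces.  Passing tests therefore
validate the statistical machinery under its own model assumptions; they do
not certify behaviour on real embryo libraries, where mapping artefacts and
violations of the NB model add error modes of their own.

## Numerical choices and degenerate inputs

Dispersions below 1e-12 are treated as Poisson.  A degenerate null
(sim_sd = 0, possible only for near-constant simulations) is floored at
1e-8 and flagged.  Trend coefficients are clamped non-negative by NNLS
rather than post-hoc truncation.  Untested features carry NaN statistics and
`tested = False`; features with zero pooled mean are never simulated.
Problem sizes in the test suite (2000-feature matrices, 50 replicate null
runs, 1000-iteration nulls) were chosen so the full statistical contracts —
calibration, FDR control, power, topology — are measured with useful
precision while the whole suite stays desk-scale.

## Known limitations

* The 1/N² weight is a heuristic shrinkage of ambiguous evidence, not an EM
  re-assignment; strongly shared loci are systematically under-counted
  relative to an EM estimator.
* The dispersion floor plus 4-df moment estimates make the test
  conservative (~0.038 observed type-I at nominal 0.05 under the default
  conditions); with larger n the gap closes.
* The pooled-mean null assumes exchangeable library depths after
  normalization; extreme depth imbalance would call for simulating at
  per-sample scaled means.
* PC1-gene selection by loading threshold is a convention; other defensible
  rules (permutation tests on loadings) would select different boundary
  features.
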