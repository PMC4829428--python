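"""Ground-truth MZT data generation.

Emulates the statistical structure the analysis assumes: negative-binomial
counts whose dispersion declines with the mean (alpha = a0 + a1/mu), a
three-group design (oocyte, wild-type 2C, mutant 2C), zygotically activated
and maternally repressed feature classes, repeat families alongside genes,
and a failed-MZT mutant whose condition means are the mixture
lambda * oocyte + (1 - lambda) * wt2C — lambda near 1 encodes a mutant that
retained the maternal transcriptome and failed zygotic activation.  Also
simulates multi-mapped alignment-hit records together with a brute-force
counting oracle, so the 1/N^2 quantifier can be verified read by read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import GENE_LOCUS, REPEAT_FAMILY, FeatureIndex
from .de_core import sample_nb
from .quantify import CountMatrix

OOCYTE = "oocyte"
WT2C = "wt2C"
MUT2C = "mut2C"

#: Default distribution of N, the number of distinct features co-hit by a
#: multi-mapping read (most reads unique, a tail of ambiguous ones).
DEFAULT_MULTIMAP_PROFILE: dict[int, float] = {1: 0.70, 2: 0.15, 3: 0.10, 5: 0.05}

CLASS_CONSTANT = "constant"
CLASS_ACTIVATED = "zygotic_activated"
CLASS_REPRESSED = "maternal_repressed"


@dataclass
class SimDesign:
    """Three-condition MZT simulation design.

    ``mixture_lambda`` blends the mutant-2C mean between oocyte (lambda=1)
    and wild-type 2C (lambda=0); ``trend`` is the (a0, a1) dispersion-mean
    relationship the counts are drawn under; ``libsize`` multiplies each
    sample's means to emulate unequal sequencing depth.
    """

    n_per_condition: int = 3
    mixture_lambda: float = 0.8
    trend: tuple[float, float] = (0.05, 2.0)
    libsize: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    conditions: tuple[str, str, str] = (OOCYTE, WT2C, MUT2C)

    def __post_init__(self):
        if not 0.0 <= self.mixture_lambda <= 1.0:
            raise ValueError("mixture_lambda must lie in [0, 1]")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if any(v <= 0 for v in self.libsize.values()):
            raise ValueError("library-size multipliers must be positive")

    def sample_ids(self) -> list[str]:
        return [f"{c}_{i + 1}" for c in self.conditions for i in range(self.n_per_condition)]

    def design_map(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids()}


def make_truth(
    n_genes: int = 2000,
    n_repeats: int = 100,
    frac_activated: float = 0.2,
    frac_repressed: float = 0.2,
    fold_range: tuple[float, float] = (4.0, 16.0),
    mean_range: tuple[float, float] = (20.0, 2000.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth feature table for the MZT scenario.

    Baseline (oocyte) means are log-uniform over ``mean_range``; fold
    changes (wt2C vs oocyte) are log2-uniform over ``fold_range`` with
    positive sign for zygotically activated and negative for maternally
    repressed features.  Class counts are allocated deterministically
    (exactly round(frac * n) per kind); randomness affects only the drawn
    means and fold sizes, so the same seed reproduces the table exactly.
    """
    if frac_activated < 0 or frac_repressed < 0 or frac_activated + frac_repressed > 1:
        raise ValueError("class fractions must be non-negative and sum to <= 1")
    if fold_range[0] < 1 or fold_range[1] < fold_range[0]:
        raise ValueError("fold_range must be >= 1 and ordered")
    if mean_range[0] <= 0 or mean_range[1] < mean_range[0]:
        raise ValueError("mean_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    rows = []
    for kind, n, prefix in ((GENE_LOCUS, n_genes, "gene"), (REPEAT_FAMILY, n_repeats, "rep")):
        n_act = round(frac_activated * n)
        n_rep = round(frac_repressed * n)
        classes = (
            [CLASS_ACTIVATED] * n_act + [CLASS_REPRESSED] * n_rep
            + [CLASS_CONSTANT] * (n - n_act - n_rep)
        )
        means = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n))
        lfc_mag = rng.uniform(np.log2(fold_range[0]), np.log2(fold_range[1]), size=n)
        for i in range(n):
            cls = classes[i]
            lfc = {CLASS_ACTIVATED: lfc_mag[i], CLASS_REPRESSED: -lfc_mag[i]}.get(cls, 0.0)
            rows.append(
                (f"{prefix}{i + 1:05d}", kind, float(means[i]), cls, float(lfc))
            )
    truth = pd.DataFrame(
        rows, columns=["feature_id", "kind", "baseline_mean", "reg_class", "true_log2fc"]
    ).set_index("feature_id")
    truth.attrs["multimap_profile"] = dict(DEFAULT_MULTIMAP_PROFILE)
    return truth


def condition_means(truth: pd.DataFrame, design: SimDesign) -> pd.DataFrame:
    """Expected normalized mean of every feature in each condition."""
    oo = truth["baseline_mean"].values
    wt = oo * np.exp2(truth["true_log2fc"].values)
    lam = design.mixture_lambda
    mut = lam * oo + (1.0 - lam) * wt
    return pd.DataFrame({OOCYTE: oo, WT2C: wt, MUT2C: mut}, index=truth.index)


def simulate_count_matrix(truth: pd.DataFrame, design: SimDesign) -> CountMatrix:
    """Draw the counts matrix: NB(mean * libsize, a0 + a1/mean) per cell."""
    rng = np.random.default_rng(design.seed)
    cmeans = condition_means(truth, design)
    a0, a1 = design.trend
    samples = design.sample_ids()
    dmap = design.design_map()
    cols = {}
    for s in samples:
        mu = cmeans[dmap[s]].values
        lib = design.libsize.get(s, 1.0)
        disp = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-300), 0.0)
        cols[s] = sample_nb(rng, mu * lib, disp).astype(float)
    counts = pd.DataFrame(cols, index=truth.index)
    kinds = truth["kind"].to_dict()
    return CountMatrix(counts=counts, design=dmap, feature_kinds=kinds)


def simulate_alignment_hits(
    n_reads: int,
    index: FeatureIndex,
    multimap_profile: dict[int, float] | None = None,
    seed: int = 0,
    samples: tuple[str, ...] = ("s1",),
) -> tuple[pd.DataFrame, CountMatrix]:
    """Simulated multi-mapped hit records plus their brute-force count oracle.

    Per read: a sample (round-robin), a multiplicity N drawn from
    ``multimap_profile``, and N distinct features chosen uniformly from the
    index.  The oracle matrix is accumulated by direct per-read enumeration
    of the 1/N^2 gene rule and repeat-name binning, independently of the
    quantify module.  Returned hits have one row per (read, feature), rows
    of one read contiguous, so the frame can be written as a hit TSV and fed
    straight to the counter.
    """
    profile = dict(multimap_profile or DEFAULT_MULTIMAP_PROFILE)
    if not profile or any(p < 0 for p in profile.values()):
        raise ValueError("multimap_profile must be a non-empty distribution")
    feature_ids = list(index.features)
    if not feature_ids:
        raise ValueError("feature index is empty")
    kinds = np.array([index.features[f].kind == GENE_LOCUS for f in feature_ids])
    ns = np.array(sorted(profile))
    ps = np.array([profile[n] for n in ns], dtype=float)
    ps = ps / ps.sum()
    if ns.max() > len(feature_ids):
        import warnings

        warnings.warn("multimap N exceeds feature count; capping at the index size")
        ns = np.minimum(ns, len(feature_ids))
    rng = np.random.default_rng(seed)
    fpos = {fid: i for i, fid in enumerate(feature_ids)}
    mat = np.zeros((len(feature_ids), len(samples)))
    rows = []
    drawn_n = rng.choice(ns, size=n_reads, p=ps)
    for r in range(n_reads):
        sample = samples[r % len(samples)]
        j = r % len(samples)
        chosen = rng.choice(len(feature_ids), size=int(drawn_n[r]), replace=False)
        read_id = f"read{r + 1:07d}"
        for ci in chosen:
            rows.append((read_id, sample, feature_ids[ci]))
        # brute-force oracle: independent re-derivation of the weighting rules
        gene_hits = [ci for ci in chosen if kinds[ci]]
        rep_hits = [ci for ci in chosen if not kinds[ci]]
        if gene_hits:
            w = 1.0 / (len(gene_hits) ** 2)
            for ci in sorted(gene_hits, key=lambda c: feature_ids[c]):
                mat[ci, j] += w
        if rep_hits:
            w = 1.0 / (len(rep_hits) ** 2)
            for ci in sorted(rep_hits, key=lambda c: feature_ids[c]):
                mat[ci, j] += w
    hits = pd.DataFrame(rows, columns=["read_id", "sample_id", "feature_id"])
    design = {s: "cond" for s in samples}
    oracle = CountMatrix(
        counts=pd.DataFrame(mat, index=feature_ids, columns=list(samples)),
        design=design,
        feature_kinds={f: index.features[f].kind for f in feature_ids},
    )
    return hits, oracle


def write_hit_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def toy_feature_index(n_genes: int = 20, n_repeats: int = 5) -> FeatureIndex:
    """Small synthetic feature index (non-overlapping loci on one synthetic
    chromosome) for exercising the counting machinery without annotations."""
    from .annotation_io import Feature

    features = {}
    pos = 1
    for i in range(n_genes):
        fid = f"g{i + 1}"
        features[fid] = Feature(
            kind=GENE_LOCUS, name=fid, intervals=(("chrS", pos, pos + 999, "+"),)
        )
        pos += 2000
    for i in range(n_repeats):
        fid = f"R{i + 1}"
        features[fid] = Feature(
            kind=REPEAT_FAMILY,
            name=fid,
            intervals=(
                ("chrS", pos, pos + 199, "+"),
                ("chrS", pos + 1000, pos + 1199, "-"),
            ),
        )
        pos += 2000
    return FeatureIndex(features=features)
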