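"""Monte-Carlo negative-binomial differential expression.

The test asks whether a feature's fold change between two conditions is
zero.  Counts are median-of-ratios normalized; a per-feature dispersion is
estimated by the method of moments and floored by a fitted dispersion-mean
trend alpha(mu) = a0 + a1/mu (the trend acts as the MINIMUM dispersion, so
poorly estimated features are never treated as less variable than their
expression level suggests).  The null distribution of the log2 fold-change
is obtained by simulation: in each iteration, negative-binomial counts with
the pooled mean and the effective dispersion are drawn for every sample,
averaged within condition, and the log2 ratio recorded.  The simulated
distribution is normal to a good approximation, so the observed log2
fold-change is converted to a z-score against it and to a two-tail p-value
from the standard normal.  Gene loci and repeat families are corrected
together with Benjamini-Hochberg; features whose mean raw count is below 10
in both conditions are not tested.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import GENE_LOCUS
from .quantify import CountMatrix

logger = logging.getLogger(__name__)

_POISSON_ALPHA = 1e-12  # below this, NB sampling degenerates to Poisson
_MIN_SIM_SD = 1e-8


# ---------------------------------------------------------------------------
# Configuration and result records
# ---------------------------------------------------------------------------


@dataclass
class DEConfig:
    """Test configuration.

    ``min_raw_count`` (10) and ``alpha_sig`` (0.05) are the published filter
    and significance threshold; iterations, pseudocount and seed are exposed
    because they are not stated by the method's description.
    ``constant_dispersion``, if set, bypasses the trend fit and floors every
    feature's dispersion at that value instead.
    """

    iterations: int = 1000
    pseudocount: float = 1.0
    min_raw_count: float = 10.0
    alpha_sig: float = 0.05
    seed: int = 0
    constant_dispersion: float | None = None

    def __post_init__(self):
        if self.iterations < 100:
            raise ValueError("iterations must be >= 100")
        if self.pseudocount <= 0 or self.min_raw_count <= 0 or not 0 < self.alpha_sig < 1:
            raise ValueError("pseudocount, min_raw_count and alpha_sig must be positive")


@dataclass
class SizeFactors:
    factors: dict[str, float]

    def __post_init__(self):
        vals = np.array(list(self.factors.values()), dtype=float)
        if (vals <= 0).any():
            raise ValueError("size factors must be positive")
        gm = math.exp(np.log(vals).mean())
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"size factors must have geometric mean 1 (got {gm})")

    def __getitem__(self, sample_id: str) -> float:
        return self.factors[sample_id]


@dataclass
class DispersionTrend:
    """alpha(mu) = a0 + a1/mu — non-increasing in mu, positive for mu > 0."""

    a0: float
    a1: float

    def __post_init__(self):
        if self.a0 < 0 or self.a1 < 0:
            raise ValueError("trend coefficients must be non-negative")

    def evaluate(self, mu: float | np.ndarray) -> float | np.ndarray:
        return self.a0 + self.a1 / mu


@dataclass
class FeatureEstimate:
    feature_id: str
    mean_per_condition: dict[str, float]
    pooled_mean: float
    observed_dispersion: float
    effective_dispersion: float | None = None


@dataclass
class NullDistribution:
    sim_mean: float
    sim_sd: float
    iterations: int
    seed: int
    degenerate: bool = False


@dataclass
class DERecord:
    feature_id: str
    kind: str
    mean_a: float
    mean_b: float
    log2fc: float
    z: float
    p: float
    adj_p: float
    significant: bool
    tested: bool


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def compute_size_factors(matrix: CountMatrix) -> SizeFactors:
    """DESeq-style median-of-ratios size factors, rescaled to geometric mean 1.

    The per-feature reference is the geometric mean across samples over
    features positive in every sample; each sample's factor is the median of
    its ratios to the reference.  If no feature is positive everywhere, falls
    back to per-sample medians of nonzero counts (with a warning).
    """
    counts = matrix.counts.values
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        logc = np.log(counts[all_pos])
        ref = logc.mean(axis=1)  # log geometric mean per feature
        raw = np.exp(np.median(logc - ref[:, None], axis=0))
    else:
        warnings.warn(
            "no feature positive in all samples; using per-sample median of nonzero counts"
        )
        raw = np.array(
            [np.median(col[col > 0]) if (col > 0).any() else 1.0 for col in counts.T]
        )
    raw = raw / math.exp(np.log(raw).mean())
    return SizeFactors(factors=dict(zip(matrix.sample_ids, raw)))


def normalize_counts(matrix: CountMatrix, factors: SizeFactors) -> CountMatrix:
    """Divide each sample's counts by its size factor."""
    f = np.array([factors[s] for s in matrix.sample_ids])
    return CountMatrix(
        counts=matrix.counts / f,
        design=dict(matrix.design),
        feature_kinds=dict(matrix.feature_kinds),
    )


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


def estimate_feature(
    matrix_norm: CountMatrix,
    matrix_raw: CountMatrix,
    design: Mapping[str, str],
    feature_id: str,
    trend: DispersionTrend | None = None,
) -> FeatureEstimate:
    """Per-feature condition means, pooled mean and moment dispersion.

    The dispersion alpha_obs = max(0, (s^2 - mu)/mu^2) uses the pooled
    within-condition sample variance s^2 (condition means subtracted, pooled
    degrees of freedom) and the pooled mean mu over all samples — the moment
    inversion of Var = mu + alpha*mu^2.  When a trend is supplied the
    effective dispersion is floored at the trend's prediction.
    """
    samples = matrix_norm.sample_ids
    x = matrix_norm.counts.loc[feature_id].values.astype(float)
    conditions = sorted({design[s] for s in samples})
    means = {}
    ss = 0.0
    dof = 0
    for c in conditions:
        idx = [i for i, s in enumerate(samples) if design[s] == c]
        xc = x[idx]
        means[c] = float(xc.mean())
        ss += float(((xc - xc.mean()) ** 2).sum())
        dof += len(xc) - 1
    mu = float(x.mean())
    if mu <= 0 or dof <= 0:
        alpha_obs = 0.0
    else:
        s2 = ss / dof
        alpha_obs = max(0.0, (s2 - mu) / (mu * mu))
    est = FeatureEstimate(
        feature_id=feature_id,
        mean_per_condition=means,
        pooled_mean=mu,
        observed_dispersion=alpha_obs,
    )
    if trend is not None and mu > 0:
        est.effective_dispersion = max(alpha_obs, float(trend.evaluate(mu)))
    return est


def fit_dispersion_trend(estimates: Sequence[FeatureEstimate]) -> DispersionTrend:
    """Least-squares fit of alpha(mu) = a0 + a1/mu with a0, a1 >= 0.

    Fitted over features with positive pooled mean (zero moment estimates are
    kept: they are informative boundary observations, and dropping them would
    bias the trend upward).  Requires at least 20 features with a strictly
    positive dispersion estimate among them.
    """
    mus = np.array([e.pooled_mean for e in estimates])
    alphas = np.array([e.observed_dispersion for e in estimates])
    use = mus > 0
    if int(((alphas > 0) & use).sum()) < 20:
        raise ValueError(
            "too few features with positive mean and dispersion to fit the trend; "
            "set DEConfig.constant_dispersion to override with a constant"
        )
    A = np.column_stack([np.ones(use.sum()), 1.0 / mus[use]])
    coef, _ = optimize.nnls(A, alphas[use])
    return DispersionTrend(a0=float(coef[0]), a1=float(coef[1]))


# ---------------------------------------------------------------------------
# Negative-binomial sampling (shared with the synthetic-data generator)
# ---------------------------------------------------------------------------


def sample_nb(
    rng: np.random.Generator,
    mean: float | np.ndarray,
    dispersion: float | np.ndarray,
    size=None,
) -> np.ndarray:
    """Draw NB counts parameterized by (mean, dispersion): Var = mu + alpha*mu^2.

    alpha = 0 degenerates to Poisson.  The (mean, dispersion) form is the
    single conversion point to numpy's (n, p) parameterization, shared by the
    tester and the simulator so the two cannot drift apart.
    """
    mean = np.asarray(mean, dtype=float)
    dispersion = np.asarray(dispersion, dtype=float)
    pois = dispersion <= _POISSON_ALPHA
    if np.all(pois):
        return rng.poisson(mean, size=size)
    r = 1.0 / np.maximum(dispersion, _POISSON_ALPHA)
    p = r / (r + mean)
    out = rng.negative_binomial(r, p, size=size)
    if np.any(pois):
        pois_draws = rng.poisson(np.broadcast_to(mean, out.shape))
        out = np.where(np.broadcast_to(pois, out.shape), pois_draws, out)
    return out


def simulate_null_logfc(
    mu: float,
    alpha_eff: float,
    n_a: int,
    n_b: int,
    config: DEConfig,
    rng: np.random.Generator,
) -> NullDistribution:
    """Monte-Carlo null distribution of the log2 fold-change at mean ``mu``.

    Each iteration draws ``n_a + n_b`` NB(mu, alpha_eff) counts, averages them
    into the two conditions and records log2((avg_b + pc)/(avg_a + pc)).
    Returns the sample mean and sd of the iterations.
    """
    if mu <= 0:
        raise ValueError("null simulation requires mu > 0")
    it = config.iterations
    draws = sample_nb(rng, mu, alpha_eff, size=(it, n_a + n_b)).astype(float)
    avg_a = draws[:, :n_a].mean(axis=1)
    avg_b = draws[:, n_a:].mean(axis=1)
    lfc = np.log2((avg_b + config.pseudocount) / (avg_a + config.pseudocount))
    sd = float(lfc.std(ddof=1))
    degenerate = sd <= 0
    if degenerate:
        sd = _MIN_SIM_SD
        logger.warning("degenerate null (sd=0) at mu=%g alpha=%g", mu, alpha_eff)
    return NullDistribution(
        sim_mean=float(lfc.mean()), sim_sd=sd, iterations=it,
        seed=config.seed, degenerate=degenerate,
    )


def test_feature(obs_log2fc: float, null: NullDistribution) -> tuple[float, float]:
    """z-score of the observed log2 fold-change against its Monte-Carlo null,
    and the two-tail normal p-value."""
    if null.sim_sd <= 0:
        raise ValueError("null sd must be positive")
    z = (obs_log2fc - null.sim_mean) / null.sim_sd
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


# ---------------------------------------------------------------------------
# The full pairwise test
# ---------------------------------------------------------------------------


def run_differential_expression(
    matrix: CountMatrix,
    cond_a: str,
    cond_b: str,
    config: DEConfig | None = None,
) -> list[DERecord]:
    """Pairwise Monte-Carlo NB test of ``cond_b`` against ``cond_a``.

    Pipeline: (1) features with mean raw count < ``min_raw_count`` in both
    conditions are not tested; (2) size factors and normalization are
    computed on the two-condition submatrix; (3) the dispersion trend is fit
    on tested features; (4) each tested feature gets an observed log2
    fold-change, a simulated null and a z/p pair; (5) genes and repeat
    families enter ONE Benjamini-Hochberg correction; (6) significance means
    adjusted p < ``alpha_sig``.  Per-feature random substreams derive from
    (seed, feature row position), so results do not depend on iteration
    order.  Positive log2fc means enrichment in ``cond_b``.
    """
    config = config or DEConfig()
    samples_a = matrix.condition_samples(cond_a)
    samples_b = matrix.condition_samples(cond_b)
    if not samples_a or not samples_b:
        raise ValueError(f"conditions {cond_a!r}/{cond_b!r} must each have >= 1 sample")
    samples = samples_a + samples_b
    sub_design = {s: matrix.design[s] for s in samples}
    sub = CountMatrix(
        counts=matrix.counts[samples],
        design=sub_design,
        feature_kinds=dict(matrix.feature_kinds),
    )

    raw = sub.counts.values
    ia = [sub.sample_ids.index(s) for s in samples_a]
    ib = [sub.sample_ids.index(s) for s in samples_b]
    raw_mean_a = raw[:, ia].mean(axis=1)
    raw_mean_b = raw[:, ib].mean(axis=1)
    tested_mask = (raw_mean_a >= config.min_raw_count) | (raw_mean_b >= config.min_raw_count)
    n_tested = int(tested_mask.sum())
    logger.info(
        "%s vs %s: %d/%d features pass the raw-count filter",
        cond_a, cond_b, n_tested, len(tested_mask),
    )
    if n_tested == 0:
        warnings.warn("all features filtered; nothing tested")

    factors = compute_size_factors(sub)
    norm = normalize_counts(sub, factors)
    norm_vals = norm.counts.values
    na, nb = len(ia), len(ib)

    feature_ids = sub.feature_ids
    estimates: dict[str, FeatureEstimate] = {}
    for i, fid in enumerate(feature_ids):
        if not tested_mask[i]:
            continue
        estimates[fid] = estimate_feature(norm, sub, sub_design, fid, trend=None)

    if n_tested:
        if config.constant_dispersion is not None:
            trend = None
            floor_const = float(config.constant_dispersion)
        else:
            trend = fit_dispersion_trend(list(estimates.values()))
            floor_const = None

    records: list[DERecord] = []
    pvals: list[float] = []
    tested_idx: list[int] = []
    for i, fid in enumerate(feature_ids):
        kind = sub.feature_kinds.get(fid, GENE_LOCUS)
        if not tested_mask[i]:
            records.append(
                DERecord(fid, kind, float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), float("nan"),
                         significant=False, tested=False)
            )
            continue
        est = estimates[fid]
        mean_a = est.mean_per_condition[cond_a]
        mean_b = est.mean_per_condition[cond_b]
        mu = est.pooled_mean
        if floor_const is not None:
            alpha_eff = max(est.observed_dispersion, floor_const)
        else:
            alpha_eff = max(est.observed_dispersion, float(trend.evaluate(mu)))
        est.effective_dispersion = alpha_eff
        obs_lfc = math.log2((mean_b + config.pseudocount) / (mean_a + config.pseudocount))
        rng = np.random.default_rng([config.seed, i])
        null = simulate_null_logfc(mu, alpha_eff, na, nb, config, rng)
        z, p = test_feature(obs_lfc, null)
        records.append(
            DERecord(fid, kind, mean_a, mean_b, obs_lfc, z, p,
                     adj_p=float("nan"), significant=False, tested=True)
        )
        pvals.append(p)
        tested_idx.append(len(records) - 1)

    if pvals:
        adj = benjamini_hochberg(pvals)  # genes and repeats corrected together
        for k, ridx in enumerate(tested_idx):
            rec = records[ridx]
            rec.adj_p = float(adj[k])
            rec.significant = rec.adj_p < config.alpha_sig
    return records


def de_table(records: Sequence[DERecord]) -> pd.DataFrame:
    """DE records as a DataFrame in record order."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "kind": [r.kind for r in records],
            "mean_a": [r.mean_a for r in records],
            "mean_b": [r.mean_b for r in records],
            "log2fc": [r.log2fc for r in records],
            "z": [r.z for r in records],
            "p": [r.p for r in records],
            "adj_p": [r.adj_p for r in records],
            "significant": [r.significant for r in records],
            "tested": [r.tested for r in records],
        }
    ).set_index("feature_id")


def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    de_table(records).to_csv(path, sep="\t", float_format="%.10g")
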