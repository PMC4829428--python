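"""End-to-end pipeline: count -> test -> compare/cluster/PCA/heatmap.

Every stage is a pure function of (inputs, config, seed); each written
artifact gets a JSON provenance sidecar carrying the config hash and seed,
and rerunning with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotation_io import FeatureIndex
from .de_core import (
    DEConfig,
    compute_size_factors,
    de_table,
    normalize_counts,
    run_differential_expression,
)
from .mzt_analysis import (
    classify_comparison,
    hierarchical_cluster_samples,
    log_transform,
    principal_components,
    select_pc1_features,
    standardized_heatmap,
)
from .quantify import CountMatrix, count_alignments

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    design: str  # design TSV path
    counts: str | None = None  # pre-computed count matrix TSV
    hits: str | None = None  # or a hit TSV to count (requires index)
    index: str | None = None  # feature-index TSV
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    iterations: int = 1000
    pseudocount: float = 1.0
    min_raw_count: float = 10.0
    alpha_sig: float = 0.05
    min_overlap: float = 0.5
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    k_sd: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.comparisons = [tuple(c) for c in cfg.comparisons]
        return cfg

    def de_config(self) -> DEConfig:
        return DEConfig(
            iterations=self.iterations,
            pseudocount=self.pseudocount,
            min_raw_count=self.min_raw_count,
            alpha_sig=self.alpha_sig,
            seed=self.seed,
        )

    def validate(self) -> None:
        if self.counts is None and (self.hits is None or self.index is None):
            raise ValueError("config needs either 'counts' or both 'hits' and 'index'")
        for name in ("design", "counts", "hits", "index"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config path {name}={p!r} does not exist")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_sidecar(artifact: Path, config: PipelineConfig, stage: str) -> None:
    sidecar = artifact.with_suffix(artifact.suffix + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {"stage": stage, "config_hash": config.digest(), "seed": config.seed,
             "version": __version__},
            indent=2,
        )
        + "\n"
    )


def _read_design(path: str | Path) -> dict[str, str]:
    design = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "condition"]:
            raise ValueError(f"{path}: expected header sample_id<TAB>condition")
        for line in fh:
            if line.strip():
                s, c = line.rstrip("\n").split("\t")
                design[s] = c
    return design


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages, writing TSV artifacts under ``out_dir``.

    Stage order: count (if starting from hits) -> differential expression
    per configured comparison -> comparison summaries -> sample dendrogram
    -> PCA -> PC1 feature set -> standardized heat-map matrix.  A stage
    failure aborts with the stage name; completed outputs are preserved.
    """
    config.validate()
    design = _read_design(config.design)
    conditions = set(design.values())
    for a, b in config.comparisons:
        if a not in conditions or b not in conditions:
            raise ValueError(f"comparison ({a}, {b}): condition not present in design")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.counts is not None:
            stage = "load-counts"
            matrix = CountMatrix.from_tsv(config.counts, config.design)
        else:
            stage = "count"
            index = FeatureIndex.from_tsv(config.index)
            matrix = count_alignments(config.hits, index, design, config.min_overlap)
            matrix.to_tsv(out / "counts.tsv")
            _write_sidecar(out / "counts.tsv", config, stage)

        de_cfg = config.de_config()
        summaries = []
        for a, b in config.comparisons:
            stage = f"de:{a}-vs-{b}"
            records = run_differential_expression(matrix, a, b, de_cfg)
            path = out / f"de_{a}_vs_{b}.tsv"
            de_table(records).to_csv(path, sep="\t", float_format="%.10g")
            _write_sidecar(path, config, stage)
            stage = f"compare:{a}-vs-{b}"
            s = classify_comparison(records, a, b)
            summaries.append(s)
            n_tested = sum(r.tested for r in records)
            n_sig = sum(r.significant for r in records)
            logger.info(
                "%s vs %s: %d tested, %d significant (%d/%d genes up/down, %d/%d repeats)",
                a, b, n_tested, n_sig, s.genes_up, s.genes_down, s.repeats_up, s.repeats_down,
            )
        if summaries:
            path = out / "comparisons.tsv"
            with open(path, "w") as fh:
                fh.write("cond_a\tcond_b\tgenes_up\tgenes_down\trepeats_up\trepeats_down\n")
                for s in summaries:
                    fh.write(
                        f"{s.comparison[0]}\t{s.comparison[1]}\t{s.genes_up}\t"
                        f"{s.genes_down}\t{s.repeats_up}\t{s.repeats_down}\n"
                    )
            _write_sidecar(path, config, "compare")

        stage = "normalize"
        factors = compute_size_factors(matrix)
        norm = normalize_counts(matrix, factors)
        expr = log_transform(norm, config.pseudocount)

        stage = "cluster"
        dend = hierarchical_cluster_samples(expr, config.cluster_metric, config.cluster_linkage)
        (out / "samples.nwk").write_text(dend.newick + "\n")
        _write_sidecar(out / "samples.nwk", config, stage)

        stage = "pca"
        pca = principal_components(expr)
        pca.sample_scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.10g")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", float_format="%.10g")
        with open(out / "pca_variance.tsv", "w") as fh:
            fh.write("component\tvariance_fraction\n")
            for k, v in enumerate(pca.variance_fraction):
                fh.write(f"PC{k + 1}\t{v:.10g}\n")
        for p in ("pca_scores.tsv", "pca_loadings.tsv", "pca_variance.tsv"):
            _write_sidecar(out / p, config, stage)

        stage = "heatmap"
        pc1_features = select_pc1_features(pca, config.k_sd)
        if pc1_features:
            hm = standardized_heatmap(expr, pc1_features)
            hm.values.to_csv(out / "heatmap.tsv", sep="\t", float_format="%.10g")
            _write_sidecar(out / "heatmap.tsv", config, stage)
        else:
            logger.warning("no features passed the PC1 loading threshold; heatmap skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
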