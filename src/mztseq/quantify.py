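"""Multi-mapping-aware read counting.

A read with several equally best alignments is down-weighted rather than
discarded: if its alignments overlap N distinct gene loci, each locus
receives 1/N^2 of a count, so the read's total gene mass is 1/N (a unique
read contributes a full count, an ambiguous one progressively less).
Repeat elements are binned by repeat name before the same rule is applied —
multiple alignments to same-name copies count as ONE hit to that family.
Gene and repeat tallies are kept independent: a read overlapping both a gene
locus and a repeat family contributes to both tables with separate N values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

from .annotation_io import GENE_LOCUS, FeatureIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadHits:
    """Feature memberships of one read: deduplicated sets of gene loci and
    repeat families its alignments overlap."""

    read_id: str
    gene_loci: frozenset[str]
    repeat_names: frozenset[str]


@dataclass
class CountMatrix:
    """Features x samples table of (possibly fractional) weighted counts.

    ``counts`` is a pandas DataFrame indexed by feature id with one column
    per sample; ``design`` maps sample id to condition label;
    ``feature_kinds`` maps feature id to ``gene_locus``/``repeat_family``.
    """

    counts: pd.DataFrame
    design: dict[str, str]
    feature_kinds: dict[str, str] = field(default_factory=dict)
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate feature or sample ids in count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = [s for s in self.counts.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        for fid in self.counts.index:
            self.feature_kinds.setdefault(fid, GENE_LOCUS)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.design[s] == condition]

    def to_tsv(self, counts_path: str | Path, design_path: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.insert(0, "kind", [self.feature_kinds[f] for f in out.index])
        out.to_csv(counts_path, sep="\t", index_label="feature_id", float_format="%.17g")
        if design_path is not None:
            with open(design_path, "w") as fh:
                fh.write("sample_id\tcondition\n")
                for s in self.sample_ids:
                    fh.write(f"{s}\t{self.design[s]}\n")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, design_path: str | Path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
        kinds = {}
        if "kind" in df.columns:
            kinds = df["kind"].to_dict()
            df = df.drop(columns="kind")
        design_df = pd.read_csv(design_path, sep="\t", index_col="sample_id")
        design = design_df["condition"].to_dict()
        return cls(counts=df.astype(float), design=design, feature_kinds=kinds)


# ---------------------------------------------------------------------------
# Per-read assignment and weighting
# ---------------------------------------------------------------------------


def assign_read_hits(
    alignments_of_one_read: Iterable[tuple[str, int, int, str]],
    index: FeatureIndex,
    min_overlap: float = 0.5,
    read_id: str = "",
) -> ReadHits:
    """Collect the gene loci and repeat families hit by one read's alignments.

    A feature is hit when an alignment (1-based closed ``(chrom, start, end,
    strand)``) overlaps any of its intervals by at least ``min_overlap`` of
    the alignment length.  Counting is unstranded.
    """
    trees = index.interval_trees()
    genes: set[str] = set()
    repeat_fams: set[str] = set()
    for chrom, start, end, _strand in alignments_of_one_read:
        tree = trees.get(chrom)
        if tree is None:
            continue
        aln_len = end - start + 1
        for iv in tree.overlap(start, end + 1):
            ov = min(end + 1, iv.end) - max(start, iv.begin)
            if ov >= min_overlap * aln_len:
                fid = iv.data
                if index.features[fid].kind == GENE_LOCUS:
                    genes.add(fid)
                else:
                    repeat_fams.add(fid)
    return ReadHits(read_id=read_id, gene_loci=frozenset(genes), repeat_names=frozenset(repeat_fams))


def weight_hits(hits: ReadHits) -> list[tuple[str, float]]:
    """Weight one read's hits by the 1/N^2 rule, genes and repeats independently.

    With ``N = |gene_loci|`` each gene locus receives 1/N^2 (total gene mass
    1/N); likewise for repeat families with their own N.
    """
    out: list[tuple[str, float]] = []
    n_gene = len(hits.gene_loci)
    if n_gene:
        w = 1.0 / (n_gene * n_gene)
        out.extend((fid, w) for fid in sorted(hits.gene_loci))
    n_rep = len(hits.repeat_names)
    if n_rep:
        w = 1.0 / (n_rep * n_rep)
        out.extend((fid, w) for fid in sorted(hits.repeat_names))
    return out


# ---------------------------------------------------------------------------
# Streaming counters
# ---------------------------------------------------------------------------


def _iter_hit_tsv(path: str | Path) -> Iterator[tuple[str, str, list[str]]]:
    """Yield (read_id, sample_id, feature_ids) from a hit TSV, grouping
    consecutive rows of the same read (input must be read-collated)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "sample_id", "feature_id"]:
            raise ValueError(f"{path}: expected header read_id<TAB>sample_id<TAB>feature_id")
        rows = (line.rstrip("\n").split("\t") for line in fh if line.strip())
        for (read_id, sample_id), grp in itertools.groupby(rows, key=lambda r: (r[0], r[1])):
            yield read_id, sample_id, [g[2] for g in grp]


def _iter_sam_reads(
    path: str | Path,
) -> Iterator[tuple[str, list[tuple[str, int, int, str]]]]:
    """Yield (read_id, alignments) from a name-collated SAM/BAM file."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for read_id, grp in itertools.groupby(sam, key=lambda a: a.query_name):
            alns = []
            for a in grp:
                if a.is_unmapped:
                    continue
                # pysam positions are 0-based half-open -> 1-based closed
                alns.append(
                    (a.reference_name, a.reference_start + 1, a.reference_end,
                     "-" if a.is_reverse else "+")
                )
            yield read_id, alns


def count_alignments(
    source: str | Path | Mapping[str, str | Path],
    index: FeatureIndex,
    design: Mapping[str, str],
    min_overlap: float = 0.5,
) -> CountMatrix:
    """Accumulate weighted per-read hits into a features x samples matrix.

    ``source`` is either a hit-TSV path (``read_id<TAB>sample_id<TAB>
    feature_id``, read-collated; an alignment-free input for exercising the
    statistics downstream) or a mapping of sample id to a name-collated
    SAM/BAM path.  Every sample must appear in ``design``.
    """
    feature_ids = list(index.features)
    fpos = {fid: i for i, fid in enumerate(feature_ids)}
    if isinstance(source, Mapping):
        sample_ids = list(source)
    else:
        sample_ids = list(design)
    for s in sample_ids:
        if s not in design:
            raise ValueError(f"sample {s!r} missing from design")
    spos = {s: j for j, s in enumerate(sample_ids)}
    mat = np.zeros((len(feature_ids), len(sample_ids)))
    summary = {
        s: {"gene_mass": 0.0, "repeat_mass": 0.0, "reads": 0, "unassigned": 0}
        for s in sample_ids
    }

    def _accumulate(hits: ReadHits, sample_id: str) -> None:
        st = summary[sample_id]
        st["reads"] += 1
        weighted = weight_hits(hits)
        if not weighted:
            st["unassigned"] += 1
            return
        j = spos[sample_id]
        for fid, w in weighted:
            mat[fpos[fid], j] += w
            if index.features[fid].kind == GENE_LOCUS:
                st["gene_mass"] += w
            else:
                st["repeat_mass"] += w

    if isinstance(source, Mapping):
        for sample_id, path in source.items():
            for read_id, alns in _iter_sam_reads(path):
                _accumulate(assign_read_hits(alns, index, min_overlap, read_id=read_id), sample_id)
    else:
        unknown_feature = 0
        for read_id, sample_id, fids in _iter_hit_tsv(source):
            if sample_id not in spos:
                raise ValueError(f"sample {sample_id!r} missing from design")
            genes, reps = set(), set()
            for fid in fids:
                feat = index.features.get(fid)
                if feat is None:
                    unknown_feature += 1
                    continue
                (genes if feat.kind == GENE_LOCUS else reps).add(fid)
            _accumulate(
                ReadHits(read_id=read_id, gene_loci=frozenset(genes), repeat_names=frozenset(reps)),
                sample_id,
            )
        if unknown_feature:
            logger.warning("%d hit rows referenced unknown features (skipped)", unknown_feature)

    for s, st in summary.items():
        logger.info(
            "sample %s: %d reads, gene mass %.2f, repeat mass %.2f, %d unassigned",
            s, st["reads"], st["gene_mass"], st["repeat_mass"], st["unassigned"],
        )
    counts = pd.DataFrame(mat, index=feature_ids, columns=sample_ids)
    kinds = {fid: index.features[fid].kind for fid in feature_ids}
    return CountMatrix(counts=counts, design=dict(design), feature_kinds=kinds, summary=summary)
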