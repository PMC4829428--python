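"""Gene and repeat annotation ingestion.

Builds the unified feature catalog the quantifier counts against: gene loci
(all transcripts sharing a ``gene_id``, exon intervals unioned) plus repeat
families (all genomic copies of one RepeatMasker repeat name collapsed under
a single feature id).  All coordinates are stored 1-based, closed; the UCSC
rmsk table dialect (0-based, half-open) is converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

GENE_LOCUS = "gene_locus"
REPEAT_FAMILY = "repeat_family"


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered, non-overlapping exons on a single strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon start {start} > end {end}"
                )
            if prev_end is not None and start <= prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end


@dataclass(frozen=True)
class RepeatElement:
    """One genomic copy of a repeat, as annotated by RepeatMasker."""

    repeat_name: str
    repeat_class_family: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if not self.repeat_name:
            raise AnnotationError("repeat element with empty repeat_name")
        if self.start > self.end:
            raise AnnotationError(
                f"repeat {self.repeat_name} on {self.chrom}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class Feature:
    kind: str  # GENE_LOCUS or REPEAT_FAMILY
    name: str
    intervals: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, strand)


@dataclass
class FeatureIndex:
    """Unified catalog of gene loci and repeat families.

    ``features`` maps a stable feature id to its kind, display name and
    genomic intervals.  Repeat families may span chromosomes (one interval
    per genomic copy); gene loci are confined to one chromosome.
    """

    features: dict[str, Feature] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] | None = field(default=None, repr=False, compare=False)

    @property
    def n_gene_loci(self) -> int:
        return sum(1 for f in self.features.values() if f.kind == GENE_LOCUS)

    @property
    def n_repeat_families(self) -> int:
        return sum(1 for f in self.features.values() if f.kind == REPEAT_FAMILY)

    def kind_of(self, feature_id: str) -> str:
        return self.features[feature_id].kind

    def interval_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries (built lazily).

        Tree intervals are half-open ``[start, end+1)`` on the stored 1-based
        closed coordinates; payload is the feature id.
        """
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for fid, feat in self.features.items():
                for chrom, start, end, _strand in feat.intervals:
                    trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, fid)
            self._trees = trees
        return self._trees

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\tkind\tname\tchrom\tstart\tend\tstrand\n")
            for fid, feat in self.features.items():
                for chrom, start, end, strand in feat.intervals:
                    fh.write(f"{fid}\t{feat.kind}\t{feat.name}\t{chrom}\t{start}\t{end}\t{strand}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureIndex":
        feats: dict[str, tuple[str, str, list]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["feature_id", "kind", "name"]:
                raise AnnotationError(f"{path}: not a feature-index TSV")
            for line in fh:
                fid, kind, name, chrom, start, end, strand = line.rstrip("\n").split("\t")
                feats.setdefault(fid, (kind, name, []))[2].append(
                    (chrom, int(start), int(end), strand)
                )
        return cls(
            features={
                fid: Feature(kind=k, name=n, intervals=tuple(ivs))
                for fid, (k, n, ivs) in feats.items()
            }
        )


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise AnnotationError(f"GTF line {lineno}: malformed attribute string {attr_field!r}")
    return attrs


def parse_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon lines of a GTF file into transcript models.

    Only ``exon`` feature lines are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes.  Exons are collected per transcript and
    sorted by start.  Malformed lines raise :class:`AnnotationError` naming
    the line number.
    """
    # transcript_id -> [gene_id, chrom, strand, [(start, end), ...]]
    collected: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"GTF line {lineno}: expected 9 tab-separated fields")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr_field = fields[:9]
            if ftype != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_field, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise AnnotationError(
                    f"GTF line {lineno}: exon line missing gene_id/transcript_id"
                )
            tid = attrs["transcript_id"]
            try:
                exon = (int(start), int(end))
            except ValueError:
                raise AnnotationError(f"GTF line {lineno}: non-integer coordinates") from None
            entry = collected.setdefault(tid, [attrs["gene_id"], chrom, strand, []])
            if (entry[1], entry[2]) != (chrom, strand):
                raise AnnotationError(
                    f"GTF line {lineno}: transcript {tid} spans chromosomes/strands"
                )
            entry[3].append(exon)
    out = []
    for tid, (gid, chrom, strand, exons) in collected.items():
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons)),
            )
        )
    return out


def _parse_rmsk_out_line(fields: Sequence[str]) -> RepeatElement:
    # .out columns: SWscore div del ins query begin end (left) strand name class/family ...
    strand = "-" if fields[8] == "C" else "+"
    return RepeatElement(
        repeat_name=fields[9],
        repeat_class_family=fields[10],
        chrom=fields[4],
        strand=strand,
        start=int(fields[5]),
        end=int(fields[6]),
    )


def parse_repeatmasker(path: str | Path) -> list[RepeatElement]:
    """Read a RepeatMasker annotation table into repeat elements.

    Two dialects are auto-detected by column signature: the classic ``.out``
    whitespace table (three header lines; 1-based closed coordinates; strand
    ``+``/``C``) and the UCSC Genome Browser ``rmsk`` TSV dump (0-based
    half-open ``genoStart``; converted to 1-based closed on read).
    """
    elements: list[RepeatElement] = []
    with open(path) as fh:
        lines = fh.readlines()
    body: list[tuple[int, str]] = [
        (i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")
    ]
    if not body:
        return elements
    first = body[0][1]
    tabbed = first.rstrip("\n").split("\t")
    if len(tabbed) >= 13 and tabbed[9] in ("+", "-"):
        # UCSC rmsk TSV: bin swScore milliDiv milliDel milliIns genoName
        # genoStart genoEnd genoLeft strand repName repClass repFamily ...
        for lineno, ln in body:
            f = ln.rstrip("\n").split("\t")
            if len(f) < 13 or f[9] not in ("+", "-"):
                raise AnnotationError(f"rmsk TSV line {lineno}: unrecognized column layout")
            elements.append(
                RepeatElement(
                    repeat_name=f[10],
                    repeat_class_family=f[11] if len(f) == 13 else f"{f[11]}/{f[12]}",
                    chrom=f[5],
                    strand=f[9],
                    start=int(f[6]) + 1,  # 0-based half-open -> 1-based closed
                    end=int(f[7]),
                )
            )
        return elements
    # .out dialect: skip header lines (those whose begin column is not an int)
    for lineno, ln in body:
        f = ln.split()
        if len(f) < 11:
            raise AnnotationError(f"RepeatMasker .out line {lineno}: unrecognized column layout")
        try:
            int(f[5]), int(f[6])
        except ValueError:
            if f[0] in ("SW", "score") or f[1] in ("perc", "div"):
                continue  # header
            raise AnnotationError(
                f"RepeatMasker .out line {lineno}: unrecognized column layout"
            ) from None
        if f[8] not in ("+", "C"):
            raise AnnotationError(f"RepeatMasker .out line {lineno}: bad strand field {f[8]!r}")
        elements.append(_parse_rmsk_out_line(f))
    return elements


# ---------------------------------------------------------------------------
# Feature index construction
# ---------------------------------------------------------------------------


def deduplicate_transcripts(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Collapse transcripts with identical (chrom, strand, exon chain).

    The first-seen transcript of each exact exon chain survives; output keeps
    input order of survivors, so the operation is idempotent.
    """
    seen: set[tuple] = set()
    out = []
    for t in transcripts:
        key = (t.chrom, t.strand, t.exons)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based closed intervals; overlapping or bookended runs merge."""
    merged: list[list[int]] = []
    for start, end in sorted(ivs):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def build_feature_index(
    transcripts: Sequence[TranscriptModel], repeats: Sequence[RepeatElement]
) -> FeatureIndex:
    """Group transcripts into gene loci and repeat elements into families.

    A gene locus is keyed by ``gene_id`` with the union of its transcripts'
    exon intervals.  All same-name repeat elements share one repeat-family
    feature.  A repeat name that collides with a gene id gets a ``repeat:``
    prefix (with a warning) so ids stay unique.
    """
    features: dict[str, Feature] = {}

    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid, ts in by_gene.items():
        chroms = {t.chrom for t in ts}
        if len(chroms) > 1:
            raise AnnotationError(f"gene locus {gid} spans multiple chromosomes: {sorted(chroms)}")
        chrom = ts[0].chrom
        strand = sorted({t.strand for t in ts})[0]  # order-insensitive pick for mixed-strand loci
        exon_ivs = [ex for t in ts for ex in t.exons]
        intervals = tuple((chrom, s, e, strand) for s, e in _merge_intervals(exon_ivs))
        features[gid] = Feature(kind=GENE_LOCUS, name=gid, intervals=intervals)

    by_name: dict[str, list[RepeatElement]] = {}
    for r in repeats:
        by_name.setdefault(r.repeat_name, []).append(r)
    for name in sorted(by_name):
        fid = name
        if fid in features:
            fid = f"repeat:{name}"
            logger.warning("repeat name %r collides with a gene id; using feature id %r", name, fid)
        intervals = tuple(
            (r.chrom, r.start, r.end, r.strand)
            for r in sorted(by_name[name], key=lambda r: (r.chrom, r.start, r.end, r.strand))
        )
        features[fid] = Feature(kind=REPEAT_FAMILY, name=name, intervals=intervals)

    return FeatureIndex(features=features)
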