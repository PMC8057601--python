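"""Unique-read feature assignment and RPM normalization.

Assignment follows the union convention of HTSeq: a unique-mapping
fragment overlapping the intervals of exactly one feature increments that
feature; a fragment touching two or more features is ambiguous and counts
toward none; a fragment touching none is tallied as no-feature. Any base
of overlap counts — there is no minimum-overlap fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotate import FeatureAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "SampleMeta",
    "CountTable",
    "FeatureIndex",
    "assign_reads",
    "rpm_normalize",
    "iter_alignments_tsv",
    "iter_alignments_sam",
    "read_sample_sheet",
    "write_sample_sheet",
]

SUMMARY_KEYS = ("assigned", "ambiguous", "no_feature", "non_unique")


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned fragment on the concatenated two-parent reference."""

    read_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"alignment {self.read_id}: start {self.start} must be < end {self.end}"
            )


@dataclass
class SampleMeta:
    """One RNA-seq library of a reciprocal cross."""

    library_id: str
    mother: str
    father: str
    replicate: int
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.mother == self.father:
            raise ValueError(f"{self.library_id}: mother and father must differ")
        if self.replicate < 1:
            raise ValueError(f"{self.library_id}: replicate must be >= 1")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError(f"{self.library_id}: library_size must be positive")


@dataclass
class CountTable:
    """Features x libraries unique-read counts plus sample metadata."""

    counts: pd.DataFrame  # index feature_id, columns library_id
    samples: list[SampleMeta]
    features: pd.DataFrame  # index feature_id; columns genome, kind

    def __post_init__(self) -> None:
        sample_ids = [s.library_id for s in self.samples]
        if sorted(self.counts.columns) != sorted(sample_ids):
            raise ValueError("count table columns do not match the sample sheet")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = self.counts[sample_ids]

    def library_sizes(self) -> pd.Series:
        """Per-library sizes: user-supplied, else total counted reads."""
        sizes = {}
        for s in self.samples:
            sizes[s.library_id] = (
                s.library_size
                if s.library_size is not None
                else int(self.counts[s.library_id].sum())
            )
        return pd.Series(sizes, dtype=float)


class FeatureIndex:
    """Interval lookup from a merged/contrast annotation."""

    def __init__(self, features: Sequence[FeatureAnnotation], stranded: bool = False):
        self.stranded = stranded
        self.trees: dict[str, IntervalTree] = {}
        self.feature_meta = {
            f.feature_id: (f.genome, f.kind, f.strand) for f in features
        }
        for f in features:
            for iv in f.intervals:
                self.trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, f.feature_id
                )

    def overlapping(self, chrom: str, start: int, end: int, strand: str = ".") -> set[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        hits = {h.data for h in tree.overlap(start, end)}
        if self.stranded and strand in {"+", "-"}:
            hits = {h for h in hits if self.feature_meta[h][2] in {strand, "."}}
        return hits

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.trees


def assign_reads(
    alignments: Iterable[AlignmentRecord],
    annotation: Sequence[FeatureAnnotation] | FeatureIndex,
    stranded: bool = False,
) -> tuple[pd.Series, dict[str, int]]:
    """Count unique fragments per feature for one library.

    Returns the per-feature count vector (indexed by every feature in the
    annotation, zeros included) and the assignment summary with keys
    ``assigned / ambiguous / no_feature / non_unique``.
    """
    if isinstance(annotation, FeatureIndex):
        index = annotation
    else:
        index = FeatureIndex(annotation, stranded=stranded)
    counts: dict[str, int] = {fid: 0 for fid in index.feature_meta}
    summary = dict.fromkeys(SUMMARY_KEYS, 0)
    unknown_chroms: set[str] = set()
    for rec in alignments:
        if not rec.is_unique:
            summary["non_unique"] += 1
            continue
        if not index.has_chrom(rec.chrom):
            if rec.chrom not in unknown_chroms:
                unknown_chroms.add(rec.chrom)
                logger.warning(
                    "alignment chromosome %s absent from annotation; "
                    "counting as no-feature",
                    rec.chrom,
                )
            summary["no_feature"] += 1
            continue
        hits = index.overlapping(rec.chrom, rec.start, rec.end, rec.strand)
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
            summary["assigned"] += 1
        elif len(hits) == 0:
            summary["no_feature"] += 1
        else:
            summary["ambiguous"] += 1
    return pd.Series(counts, dtype=int), summary


def rpm_normalize(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Reads-per-million: ``count / library_size * 1e6`` per library."""
    sizes = library_sizes.reindex(counts.columns)
    if sizes.isna().any():
        missing = list(sizes.index[sizes.isna()])
        raise ValueError(f"missing library sizes for {missing}")
    if (sizes <= 0).any():
        bad = list(sizes.index[sizes <= 0])
        raise ValueError(f"library sizes must be positive; offending: {bad}")
    return counts.div(sizes, axis=1) * 1e6


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def iter_alignments_tsv(path: str | Path) -> Iterator[AlignmentRecord]:
    """Read the 5/6-column alignment TSV.

    Columns: read_id, chrom, start, end, unique_flag[, strand]; 0-based
    half-open coordinates; unique_flag is 1/0.
    """
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith("read_id"):
            yield _tsv_record(first)
        for line in fh:
            if line.strip():
                yield _tsv_record(line)


def _tsv_record(line: str) -> AlignmentRecord:
    parts = line.rstrip("\n").split("\t")
    strand = parts[5] if len(parts) > 5 else "."
    return AlignmentRecord(
        parts[0], parts[1], int(parts[2]), int(parts[3]),
        strand=strand, is_unique=parts[4] in {"1", "True", "true"},
    )


def iter_alignments_sam(
    path: str | Path, min_mapq: int = 30
) -> Iterator[AlignmentRecord]:
    """Read SAM/BAM, merging mate pairs into single fragments.

    A fragment is unique when its NH tag equals 1, or — if NH is absent —
    when mapping quality is at least ``min_mapq``. Mates are grouped by
    read name; a fragment spans the union of its mates' aligned blocks
    (one record per chromosome touched).
    """
    import pysam

    frags: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            frags.setdefault(aln.query_name, []).append(
                (
                    fh.get_reference_name(aln.reference_id),
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    aln.get_tag("NH") == 1
                    if aln.has_tag("NH")
                    else aln.mapping_quality >= min_mapq,
                )
            )
    for read_id, mates in frags.items():
        unique = all(m[4] for m in mates)
        by_chrom: dict[str, list] = {}
        for chrom, start, end, strand, _ in mates:
            by_chrom.setdefault(chrom, []).append((start, end, strand))
        for chrom, spans in by_chrom.items():
            yield AlignmentRecord(
                read_id,
                chrom,
                min(s for s, _, _ in spans),
                max(e for _, e, _ in spans),
                strand=spans[0][2],
                is_unique=unique,
            )


SHEET_COLUMNS = ["library_id", "mother", "father", "replicate"]


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet is missing required columns: {missing}")
    samples = []
    for _, row in df.iterrows():
        size = row.get("library_size")
        samples.append(
            SampleMeta(
                str(row["library_id"]),
                str(row["mother"]),
                str(row["father"]),
                int(row["replicate"]),
                None if size is None or pd.isna(size) else int(size),
            )
        )
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "library_id": s.library_id,
                "mother": s.mother,
                "father": s.father,
                "replicate": s.replicate,
                "library_size": s.library_size,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)
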