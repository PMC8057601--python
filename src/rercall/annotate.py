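"""Merged gene+TE annotations and concatenated two-parent contrasts.

Reads arrive aligned to a *concatenated* genome built from the two parents
of a reciprocal cross, so unique alignments identify not just a locus but
the parental haplotype it came from. This module builds the annotation that
drives that assignment:

* per genome, exon intervals are subtracted from TE spans and the two
  feature sets are merged, so that a read in an exon counts toward the gene
  while a read in a TE-containing intron counts toward the TE;
* the two per-genome annotations are concatenated under collision-free
  sequence names, each feature keeping its genome of origin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .intervals import Interval, merge_intervals, subtract_intervals, total_length

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSpec",
    "FeatureAnnotation",
    "build_union_annotation",
    "concatenate_annotations",
    "read_gene_gff3",
    "read_te_gff3",
    "read_contrast_gff3",
    "write_gff3",
    "write_feature_table",
    "read_feature_table",
]

TE_ORDERS = {"LTR", "TIR", "DHH", "LINE", "none"}


@dataclass
class GenomeSpec:
    """One parent of a contrast: genotype name plus sequence renaming.

    ``rename_map`` maps original chromosome names to names unique within
    the concatenated two-parent reference (e.g. ``chr1 -> B73_chr1``).
    """

    genotype_name: str
    chromosome_names: list[str]
    rename_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.chromosome_names:
            self.rename_map.setdefault(chrom, f"{self.genotype_name}_{chrom}")
        values = list(self.rename_map.values())
        if len(set(values)) != len(values):
            raise ValueError(
                f"rename_map for {self.genotype_name} is not injective"
            )

    def rename(self, chrom: str) -> str:
        return self.rename_map.get(chrom, f"{self.genotype_name}_{chrom}")


@dataclass
class FeatureAnnotation:
    """A gene (exon intervals) or TE (disjoined span intervals) on one genome."""

    feature_id: str
    genome: str
    kind: str  # "gene" | "TE"
    intervals: list[Interval]
    strand: str = "."
    te_order: str | None = None
    te_family: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"gene", "TE"}:
            raise ValueError(f"{self.feature_id}: kind must be 'gene' or 'TE'")
        self.intervals = merge_intervals(self.intervals)

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom if self.intervals else ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.intervals[0].start, self.intervals[-1].end)


def _check_unique_ids(features: Iterable[FeatureAnnotation]) -> None:
    seen: set[str] = set()
    for f in features:
        if f.feature_id in seen:
            raise ValueError(f"duplicate feature_id {f.feature_id!r} within a genome")
        seen.add(f.feature_id)


def build_union_annotation(
    genes: Sequence[FeatureAnnotation],
    tes: Sequence[FeatureAnnotation],
) -> list[FeatureAnnotation]:
    """Merge gene and TE annotations for one genome.

    Gene features keep their exon intervals. TE features keep their spans
    minus any exon bases, so a TE wholly inside an exon disappears (it is
    dropped from counting, with a log record). TEs overlapping an earlier
    TE in sort order are truncated against it with a warning, yielding a
    disjoint TE space on imperfect input.
    """
    _check_unique_ids(list(genes) + list(tes))
    exon_space = [iv for g in genes for iv in g.intervals]

    merged: list[FeatureAnnotation] = list(genes)
    claimed_te_space: list[Interval] = []
    for te in sorted(tes, key=lambda t: (t.chrom, t.span[0], t.feature_id)):
        reduced = subtract_intervals(te.intervals, exon_space)
        before = total_length(reduced)
        reduced2 = subtract_intervals(reduced, claimed_te_space)
        if total_length(reduced2) < before:
            warnings.warn(
                f"TE {te.feature_id} overlaps a previously placed TE; "
                "truncating against earlier records",
                stacklevel=2,
            )
        reduced = reduced2
        if not reduced:
            logger.info(
                "TE %s reduced to empty after exon subtraction; dropped",
                te.feature_id,
            )
            continue
        claimed_te_space.extend(reduced)
        merged.append(
            FeatureAnnotation(
                te.feature_id,
                te.genome,
                "TE",
                reduced,
                strand=te.strand,
                te_order=te.te_order,
                te_family=te.te_family,
            )
        )
    return merged


def concatenate_annotations(
    merged_a: Sequence[FeatureAnnotation],
    merged_b: Sequence[FeatureAnnotation],
    spec_a: GenomeSpec,
    spec_b: GenomeSpec,
) -> list[FeatureAnnotation]:
    """Combine two per-genome annotations under concatenated sequence names.

    Every feature keeps its genome of origin; renamed chromosome names must
    not collide across the two parents.
    """
    renamed_a = set(spec_a.rename_map.values())
    renamed_b = set(spec_b.rename_map.values())
    clash = renamed_a & renamed_b
    if clash:
        raise ValueError(
            f"chromosome name collision after renaming: {sorted(clash)}"
        )

    out: list[FeatureAnnotation] = []
    for feats, spec in ((merged_a, spec_a), (merged_b, spec_b)):
        for f in feats:
            out.append(
                FeatureAnnotation(
                    f.feature_id,
                    spec.genotype_name,
                    f.kind,
                    [
                        Interval(spec.rename(iv.chrom), iv.start, iv.end, iv.strand)
                        for iv in f.intervals
                    ],
                    strand=f.strand,
                    te_order=f.te_order,
                    te_family=f.te_family,
                )
            )
    _check_unique_ids(out)
    return out


# ---------------------------------------------------------------------------
# GFF3 and table I/O (1-based closed on disk, half-open in memory)
# ---------------------------------------------------------------------------


def _gff_db(path: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def read_gene_gff3(path: str | Path, genome: str) -> list[FeatureAnnotation]:
    """Read a gene/mRNA/exon GFF3 into gene features with unioned exons."""
    db = _gff_db(path)
    genes: list[FeatureAnnotation] = []
    for gene in db.features_of_type("gene"):
        exons = [
            Interval(e.seqid, e.start - 1, e.end, e.strand or ".")
            for e in db.children(gene, featuretype="exon")
        ]
        if not exons:
            # gene without exon children: use the gene span itself
            exons = [Interval(gene.seqid, gene.start - 1, gene.end, gene.strand or ".")]
        genes.append(
            FeatureAnnotation(gene.id, genome, "gene", exons, strand=gene.strand or ".")
        )
    return genes


def read_te_gff3(path: str | Path, genome: str) -> list[FeatureAnnotation]:
    """Read a one-record-per-element TE GFF3 with classification attributes."""
    db = _gff_db(path)
    tes: list[FeatureAnnotation] = []
    for rec in db.all_features():
        if rec.featuretype in {"gene", "mRNA", "exon", "CDS"}:
            continue
        order = rec.attributes.get("te_order", [None])[0] or rec.attributes.get(
            "order", [None]
        )[0]
        family = rec.attributes.get("te_family", [None])[0] or rec.attributes.get(
            "family", [None]
        )[0]
        tes.append(
            FeatureAnnotation(
                rec.id,
                genome,
                "TE",
                [Interval(rec.seqid, rec.start - 1, rec.end, rec.strand or ".")],
                strand=rec.strand or ".",
                te_order=order,
                te_family=family,
            )
        )
    return tes


def write_gff3(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    """Write features to GFF3; genes become gene+exon rows, TEs single rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            start, end = f.span
            if f.kind == "gene":
                attrs = f"ID={f.feature_id};genome={f.genome}"
                fh.write(
                    f"{f.chrom}\trercall\tgene\t{start + 1}\t{end}\t.\t{f.strand}\t.\t{attrs}\n"
                )
                for i, iv in enumerate(f.intervals, 1):
                    fh.write(
                        f"{iv.chrom}\trercall\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{f.strand}\t.\tID={f.feature_id}.exon{i};Parent={f.feature_id}\n"
                    )
            else:
                attrs = (
                    f"genome={f.genome};te_order={f.te_order or 'none'};"
                    f"te_family={f.te_family or 'none'}"
                )
                for i, iv in enumerate(f.intervals, 1):
                    fh.write(
                        f"{iv.chrom}\trercall\ttransposable_element\t{iv.start + 1}\t"
                        f"{iv.end}\t.\t{f.strand}\t.\tID={f.feature_id}.part{i};"
                        f"element_id={f.feature_id};{attrs}\n"
                    )


def read_contrast_gff3(path: str | Path) -> list[FeatureAnnotation]:
    """Re-read a contrast GFF3 written by :func:`write_gff3`."""
    db = _gff_db(path)
    feats: list[FeatureAnnotation] = []
    for gene in db.features_of_type("gene"):
        exons = [
            Interval(e.seqid, e.start - 1, e.end, e.strand or ".")
            for e in db.children(gene, featuretype="exon")
        ]
        feats.append(
            FeatureAnnotation(
                gene.id,
                gene.attributes.get("genome", ["?"])[0],
                "gene",
                exons or [Interval(gene.seqid, gene.start - 1, gene.end)],
                strand=gene.strand or ".",
            )
        )
    te_parts: dict[str, list] = {}
    for rec in db.features_of_type("transposable_element"):
        eid = rec.attributes.get("element_id", [rec.id])[0]
        te_parts.setdefault(eid, []).append(rec)
    for eid, recs in te_parts.items():
        first = recs[0]
        order = first.attributes.get("te_order", ["none"])[0]
        family = first.attributes.get("te_family", ["none"])[0]
        feats.append(
            FeatureAnnotation(
                eid,
                first.attributes.get("genome", ["?"])[0],
                "TE",
                [Interval(r.seqid, r.start - 1, r.end, r.strand or ".") for r in recs],
                strand=first.strand or ".",
                te_order=None if order == "none" else order,
                te_family=None if family == "none" else family,
            )
        )
    return feats


def write_feature_table(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    """Flat TSV: one row per feature, intervals encoded start-end;start-end."""
    with open(path, "w") as fh:
        fh.write("feature_id\tgenome\tkind\tchrom\tstrand\tintervals\tte_order\tte_family\n")
        for f in features:
            ivs = ";".join(f"{iv.start}-{iv.end}" for iv in f.intervals)
            fh.write(
                f"{f.feature_id}\t{f.genome}\t{f.kind}\t{f.chrom}\t{f.strand}\t"
                f"{ivs}\t{f.te_order or 'none'}\t{f.te_family or 'none'}\n"
            )


def read_feature_table(path: str | Path) -> list[FeatureAnnotation]:
    feats: list[FeatureAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            ivs = [
                Interval(row[idx["chrom"]], int(a), int(b), row[idx["strand"]])
                for a, b in (p.split("-") for p in row[idx["intervals"]].split(";"))
            ]
            feats.append(
                FeatureAnnotation(
                    row[idx["feature_id"]],
                    row[idx["genome"]],
                    row[idx["kind"]],
                    ivs,
                    strand=row[idx["strand"]],
                    te_order=None if row[idx["te_order"]] == "none" else row[idx["te_order"]],
                    te_family=None if row[idx["te_family"]] == "none" else row[idx["te_family"]],
                )
            )
    return feats
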