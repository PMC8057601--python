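"""End-to-end orchestration of the RER imprinting pipeline.

Stages run in order: annotation merge -> read assignment -> RER ->
dosage test -> SNP-ASE (when allele counts are supplied) -> tissue
filters -> classification -> cross-genome overlap. Every stage is a pure
function of its inputs plus configuration, so identical inputs and seed
reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    FeatureAnnotation,
    GenomeSpec,
    build_union_annotation,
    concatenate_annotations,
    read_feature_table,
    read_gene_gff3,
    read_te_gff3,
    write_feature_table,
    write_gff3,
)
from .counts import (
    CountTable,
    FeatureIndex,
    assign_reads,
    iter_alignments_sam,
    iter_alignments_tsv,
    read_sample_sheet,
)
from .downstream import consistency_overlap
from .filters import tissue_flags
from .imprint import ImprintThresholds, classify_imprinting, dosage_test
from .rer import rer_table
from .snp_ase import snp_ase_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "count_libraries"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pairwise contrast."""

    sample_sheet: str
    counts: str | None = None  # precomputed counts TSV (features x libraries)
    feature_table: str | None = None  # TSV from annotate stage
    genes_gff: dict[str, str] = field(default_factory=dict)  # genotype -> path
    tes_gff: dict[str, str] = field(default_factory=dict)
    alignments: dict[str, str] = field(default_factory=dict)  # library -> path
    allele_counts: str | None = None
    tissue_expression: str | None = None
    tissue_classes: str | None = None
    ortholog_map: str | None = None
    out_dir: str = "rercall_out"
    # thresholds
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    rer_meg: float = 0.9
    rer_peg: float = 0.1
    min_total_count: int = 10
    min_rer_reads: int = 10
    snp_hi: float = 0.85
    snp_lo: float = 0.15
    pericarp_fold: float = 2.0
    endosperm_fraction: float = 0.6
    stranded: bool = False
    paternal_te_excluded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("alpha", 0.0, 1.0), ("rer_meg", 0.0, 1.0), ("rer_peg", 0.0, 1.0),
            ("snp_hi", 0.0, 1.0), ("snp_lo", 0.0, 1.0),
            ("endosperm_fraction", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.lfc_threshold < 0 or self.pericarp_fold <= 0:
            raise ValueError("lfc_threshold must be >= 0 and pericarp_fold > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def count_libraries(
    annotation: list[FeatureAnnotation],
    alignment_paths: dict[str, str],
    samples,
    stranded: bool = False,
) -> tuple[CountTable, pd.DataFrame]:
    """Assign reads for every library and assemble the count table."""
    index = FeatureIndex(annotation, stranded=stranded)
    cols, summaries = {}, {}
    for s in samples:
        path = alignment_paths[s.library_id]
        it = (
            iter_alignments_sam(path)
            if str(path).endswith((".sam", ".bam"))
            else iter_alignments_tsv(path)
        )
        counts, summary = assign_reads(it, index, stranded=stranded)
        cols[s.library_id] = counts
        summaries[s.library_id] = summary
        if s.library_size is None:
            # default: total unique-mapped reads in the library
            s.library_size = (
                summary["assigned"] + summary["ambiguous"] + summary["no_feature"]
            )
    features = pd.DataFrame(
        {
            "genome": {f.feature_id: f.genome for f in annotation},
            "kind": {f.feature_id: f.kind for f in annotation},
        }
    )
    features.index.name = "feature_id"
    table = CountTable(pd.DataFrame(cols), list(samples), features)
    return table, pd.DataFrame(summaries).T


def _load_counts(cfg: PipelineConfig, samples) -> CountTable:
    df = pd.read_csv(cfg.counts, sep="\t", index_col=0)
    meta_cols = [c for c in ("genome", "kind") if c in df.columns]
    features = df[meta_cols].copy()
    if "genome" not in features.columns or "kind" not in features.columns:
        raise ValueError("counts TSV must carry 'genome' and 'kind' columns")
    counts = df.drop(columns=meta_cols).astype(int)
    return CountTable(counts, samples, features)


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run all stages for one contrast and write the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    samples = read_sample_sheet(cfg.sample_sheet)
    genotypes = sorted({s.mother for s in samples})

    # --- annotation + counting, or precomputed counts -----------------------
    if cfg.counts:
        table = _load_counts(cfg, samples)
        summary = None
    else:
        if cfg.feature_table:
            annotation = read_feature_table(cfg.feature_table)
        else:
            if set(cfg.genes_gff) != set(genotypes):
                raise ValueError(
                    "genes_gff must provide one GFF3 per genotype in the sample sheet"
                )
            merged = {}
            for g in genotypes:
                genes = read_gene_gff3(cfg.genes_gff[g], g)
                tes = read_te_gff3(cfg.tes_gff[g], g) if g in cfg.tes_gff else []
                merged[g] = build_union_annotation(genes, tes)
            spec_a = GenomeSpec(genotypes[0], [])
            spec_b = GenomeSpec(genotypes[1], [])
            annotation = concatenate_annotations(
                merged[genotypes[0]], merged[genotypes[1]], spec_a, spec_b
            )
            write_gff3(annotation, out / "contrast_annotation.gff3")
            write_feature_table(annotation, out / "contrast_features.tsv")
        if not cfg.alignments:
            raise ValueError("either counts or alignments must be provided")
        table, summary = count_libraries(
            annotation, cfg.alignments, samples, stranded=cfg.stranded
        )
        table.counts.to_csv(out / "counts.tsv", sep="\t")
        summary.to_csv(out / "assignment_summary.tsv", sep="\t")

    # --- RER ----------------------------------------------------------------
    rer = rer_table(table, min_reads=cfg.min_rer_reads)
    rer.to_csv(out / "rer.tsv", sep="\t")
    results["rer"] = rer

    # --- dosage test --------------------------------------------------------
    test = dosage_test(
        table,
        lfc_threshold=cfg.lfc_threshold,
        min_total_count=cfg.min_total_count,
    )
    test.to_csv(out / "dosage_test.tsv", sep="\t")
    results["test"] = test

    # --- tissue filters -----------------------------------------------------
    pericarp_flagged: set[str] = set()
    if cfg.tissue_expression and cfg.tissue_classes:
        expr = pd.read_csv(cfg.tissue_expression, sep="\t", index_col=0)
        classes = pd.read_csv(cfg.tissue_classes, sep="\t", index_col=0).iloc[:, 0]
        flags = tissue_flags(
            expr, classes, fold=cfg.pericarp_fold, fraction=cfg.endosperm_fraction
        )
        flags.to_csv(out / "tissue_flags.tsv", sep="\t")
        results["tissue_flags"] = flags
        pericarp_flagged = set(flags.index[flags["pericarp_flag"]])
        if cfg.ortholog_map:
            omap = pd.read_csv(cfg.ortholog_map, sep="\t")
            from .filters import propagate_flags

            for g in genotypes:
                if g in omap.columns and "anchor" in omap.columns:
                    pericarp_flagged |= propagate_flags(
                        flags["pericarp_flag"], omap, "anchor", g
                    )

    # --- classification -----------------------------------------------------
    calls = classify_imprinting(
        test,
        rer,
        ImprintThresholds(
            lfc_threshold=cfg.lfc_threshold,
            alpha=cfg.alpha,
            rer_meg=cfg.rer_meg,
            rer_peg=cfg.rer_peg,
            min_total_count=cfg.min_total_count,
        ),
        pericarp_flagged=pericarp_flagged,
        paternal_te_excluded=cfg.paternal_te_excluded,
    )
    calls.to_csv(out / "imprint_calls.tsv", sep="\t")
    results["calls"] = calls

    # --- SNP-ASE ------------------------------------------------------------
    if cfg.allele_counts:
        ac = pd.read_csv(cfg.allele_counts, sep="\t")
        ase = snp_ase_table(
            ac, samples, min_informative=cfg.min_rer_reads,
            hi=cfg.snp_hi, lo=cfg.snp_lo,
        )
        ase.to_csv(out / "snp_ase.tsv", sep="\t")
        results["snp_ase"] = ase

    # --- cross-genome overlap ----------------------------------------------
    if cfg.ortholog_map:
        omap = pd.read_csv(cfg.ortholog_map, sep="\t")
        g_a, g_b = genotypes
        if g_a in omap.columns and g_b in omap.columns:
            calls_a = calls[calls["genome"] == g_a]
            calls_b = calls[calls["genome"] == g_b]
            overlap = consistency_overlap(calls_a, calls_b, omap, g_a, g_b)
            overlap.to_csv(out / "overlap.tsv", sep="\t", index=False)
            results["overlap"] = overlap

    log = {
        "rercall_version": __version__,
        "seed": cfg.seed,
        "n_features": int(len(table.counts)),
        "n_libraries": int(table.counts.shape[1]),
        "categories": calls["category"].value_counts().to_dict(),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished: %s", log["categories"])
    return results
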