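"""SNP-based allele-specific expression (SNP-ASE) ratios and bias calls.

SNP-ASE assigns variant-overlapping reads to parental alleles within a
single sample, giving a maternal-allele fraction per cross direction. In
endosperm the biparental expectation is again 2/3 (two maternal copies to
one paternal). Comparing the two reciprocal directions separates
parent-of-origin effects (both directions extreme the same way) from
genotype-biased expression, where one genotype's allele dominates in both
directions and the maternal fraction therefore flips between reciprocals.
Genotype bias is invisible to RER, which averages across reciprocals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .counts import SampleMeta

__all__ = [
    "SNPASERecord",
    "compute_snp_ratio",
    "classify_snp_ase",
    "snp_ase_table",
]


@dataclass
class SNPASERecord:
    gene_id: str
    mother: str
    father: str
    maternal_reads: int
    paternal_reads: int
    ratio: float  # NaN when informative reads < minimum

    @property
    def informative(self) -> int:
        return self.maternal_reads + self.paternal_reads


def compute_snp_ratio(
    maternal_reads: int, paternal_reads: int, min_informative: int = 10
) -> float:
    """Maternal-allele fraction m/(m+p); NaN below ``min_informative`` reads."""
    if maternal_reads < 0 or paternal_reads < 0:
        raise ValueError("allele read counts must be non-negative")
    informative = maternal_reads + paternal_reads
    if informative < min_informative:
        return math.nan
    return maternal_reads / informative


def classify_snp_ase(
    ratio_cross1: float,
    ratio_cross2: float,
    hi: float = 0.85,
    lo: float = 0.15,
    genotypes: tuple[str, str] = ("A", "B"),
) -> str:
    """Classify a gene from its two reciprocal maternal-allele fractions.

    ``ratio_cross1`` is the maternal fraction when ``genotypes[0]`` is the
    mother; ``ratio_cross2`` when ``genotypes[1]`` is. Concordant extreme
    ratios indicate a parental bias; discordant extremes (> hi one way,
    < lo the other) mean one genotype's allele dominates regardless of
    direction — genotype bias, named for the favored genotype.
    """
    a, b = genotypes
    if math.isnan(ratio_cross1) or math.isnan(ratio_cross2):
        return "unassessable"
    if ratio_cross1 > hi and ratio_cross2 > hi:
        return "maternal_biased"
    if ratio_cross1 < lo and ratio_cross2 < lo:
        return "paternal_biased"
    if ratio_cross1 > hi and ratio_cross2 < lo:
        return f"genotype_biased_{a}"
    if ratio_cross1 < lo and ratio_cross2 > hi:
        return f"genotype_biased_{b}"
    return "unbiased"


def snp_ase_table(
    allele_counts: pd.DataFrame,
    samples: list[SampleMeta],
    min_informative: int = 10,
    hi: float = 0.85,
    lo: float = 0.15,
) -> pd.DataFrame:
    """Per-gene SNP-ASE ratios for both directions plus the bias class.

    ``allele_counts`` columns: gene_id, library_id, maternal_reads,
    paternal_reads. Reads are summed over replicates within a direction
    before the ratio is taken.
    """
    required = {"gene_id", "library_id", "maternal_reads", "paternal_reads"}
    missing = required - set(allele_counts.columns)
    if missing:
        raise ValueError(f"allele-count table is missing columns: {sorted(missing)}")
    meta = {s.library_id: s for s in samples}
    mothers = sorted({s.mother for s in samples})
    if len(mothers) != 2:
        raise ValueError("expected exactly two cross directions in the sample sheet")
    geno_a, geno_b = mothers

    df = allele_counts.copy()
    df["mother"] = df["library_id"].map(lambda l: meta[l].mother)
    agg = (
        df.groupby(["gene_id", "mother"])[["maternal_reads", "paternal_reads"]]
        .sum()
        .unstack("mother", fill_value=0)
    )

    rows = []
    for gene_id in agg.index:
        def reads(which: str, mother: str) -> int:
            try:
                return int(agg.loc[gene_id, (which, mother)])
            except KeyError:
                return 0

        r1 = compute_snp_ratio(
            reads("maternal_reads", geno_a), reads("paternal_reads", geno_a),
            min_informative,
        )
        r2 = compute_snp_ratio(
            reads("maternal_reads", geno_b), reads("paternal_reads", geno_b),
            min_informative,
        )
        rows.append(
            {
                "gene_id": gene_id,
                f"ratio_{geno_a}_mother": r1,
                f"ratio_{geno_b}_mother": r2,
                "classification": classify_snp_ase(
                    r1, r2, hi=hi, lo=lo, genotypes=(geno_a, geno_b)
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
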