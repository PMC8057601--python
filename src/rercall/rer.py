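"""The Reciprocal Expression Ratio (RER).

For a feature annotated on one parental genome of a reciprocal cross, RER
is the mean expression (RPM) of that feature in libraries where its genome
was inherited maternally, divided by the sum of the mean expression when
inherited maternally and paternally:

    RER = m / (m + p)

Endosperm carries two maternal genome copies and one paternal copy, so a
biparentally expressed, dosage-proportional feature has expectation
RER = 2/3 ~ 0.67; fully maternal expression gives 1 and fully paternal 0.
Unlike SNP-based allele-specific expression, RER needs no variant inside
the transcript — only unique alignability in the concatenated two-parent
reference — so it extends imprinting tests to presence/absence variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountTable, rpm_normalize

__all__ = [
    "RERRecord",
    "compute_rer",
    "assessability_filter",
    "bin_rer",
    "rer_table",
]

BIN_LABELS = (
    "strong_maternal",
    "moderate_maternal",
    "unbiased",
    "moderate_paternal",
    "strong_paternal",
)


@dataclass
class RERRecord:
    feature_id: str
    genome: str
    kind: str
    maternal_mean_rpm: float
    paternal_mean_rpm: float
    rer: float  # NaN when undefined (m + p == 0)
    n_unique_reads: int
    assessable: bool


def compute_rer(maternal_mean: float, paternal_mean: float) -> float:
    """RER = m / (m + p); NaN when both means are zero."""
    if maternal_mean < 0 or paternal_mean < 0:
        raise ValueError("mean expression must be non-negative")
    total = maternal_mean + paternal_mean
    if total == 0:
        return math.nan
    return maternal_mean / total


def assessability_filter(n_unique_reads: int, min_reads: int = 10) -> bool:
    """A feature is assessable with at least ``min_reads`` unique reads
    summed over all libraries of the contrast (threshold inclusive)."""
    return n_unique_reads >= min_reads


def bin_rer(rer: float) -> str | None:
    """Bin an RER value: strong beyond 0.9/0.1, moderate beyond 0.8/0.2.

    Returns None for undefined (NaN) input.
    """
    if rer is None or (isinstance(rer, float) and math.isnan(rer)):
        return None
    if rer > 0.9:
        return "strong_maternal"
    if rer > 0.8:
        return "moderate_maternal"
    if rer < 0.1:
        return "strong_paternal"
    if rer < 0.2:
        return "moderate_paternal"
    return "unbiased"


def rer_table(table: CountTable, min_reads: int = 10) -> pd.DataFrame:
    """Per-feature RER for one pairwise contrast.

    For each feature, libraries where the feature's genome is the mother
    contribute to the maternal mean RPM and libraries where it is the
    father to the paternal mean; replicates are averaged arithmetically.
    RER considers each genome's allele independently — no cross-genome
    matching happens here.
    """
    sizes = table.library_sizes()
    rpm = rpm_normalize(table.counts, sizes)
    genomes = table.features["genome"]

    mat_libs = {
        g: [s.library_id for s in table.samples if s.mother == g]
        for g in genomes.unique()
    }
    pat_libs = {
        g: [s.library_id for s in table.samples if s.father == g]
        for g in genomes.unique()
    }

    parts = []
    for g in genomes.unique():
        idx = genomes.index[genomes == g]
        mcols, pcols = mat_libs[g], pat_libs[g]
        m = rpm.loc[idx, mcols].mean(axis=1) if mcols else pd.Series(0.0, index=idx)
        p = rpm.loc[idx, pcols].mean(axis=1) if pcols else pd.Series(0.0, index=idx)
        n = table.counts.loc[idx, mcols + pcols].sum(axis=1).astype(int)
        total = m + p
        r = m.where(total > 0) / total.where(total > 0)
        parts.append(
            pd.DataFrame(
                {
                    "genome": g,
                    "kind": table.features.loc[idx, "kind"],
                    "maternal_mean_rpm": m,
                    "paternal_mean_rpm": p,
                    "rer": r,
                    "n_unique_reads": n,
                    "assessable": n >= min_reads,
                    "bin": [bin_rer(x) for x in r],
                },
                index=idx,
            )
        )
    out = pd.concat(parts).reindex(genomes.index)
    out.index.name = "feature_id"
    return out
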