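"""Cross-genome consistency, enrichment tests, and matTE nearest genes.

RER tests each genome's allele independently, so agreement between the two
parents of a contrast is established afterwards through an ortholog map
(anchor-genome-centric, at most one correspondence per genotype). The
module also re-implements the signed nearest-gene distance (bedtools
closest with distances reported relative to gene orientation) and wraps
the enrichment statistics used downstream: exact binomial upper tail,
Pearson chi-square on contingency tables, and Welch's t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import FeatureAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "NearestGeneResult",
    "consistency_overlap",
    "nearest_gene",
    "binomial_enrichment",
    "categorical_enrichment",
    "two_sample_mean_test",
]

IMPRINTED_CATEGORIES = {"MEG", "PEG", "matTE", "patTE"}


@dataclass
class NearestGeneResult:
    te_id: str
    gene_id: str
    signed_distance: int  # 0 when overlapping; sign relative to gene orientation
    gene_category: str | None = None


def consistency_overlap(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    col_a: str,
    col_b: str,
) -> pd.DataFrame:
    """Partition imprinted features of a contrast by cross-genome status.

    For every imprinted feature (category in MEG/PEG/matTE/patTE) in either
    call set: ``shared_imprinted`` if its counterpart exists in the other
    genome's calls and carries the same category; ``assessable_not_shared``
    if the counterpart exists in the other call table but differs;
    ``unique_to_one_genome`` if the map gives no counterpart or the
    counterpart was never assessed. Duplicate correspondences are an error.
    """
    pairs = ortholog_map[[col_a, col_b]].dropna()
    for col in (col_a, col_b):
        if pairs[col].duplicated().any():
            dup = pairs[col][pairs[col].duplicated()].iloc[0]
            raise ValueError(f"duplicate correspondence for {dup!r} in {col}")
    a_to_b = dict(zip(pairs[col_a], pairs[col_b]))
    b_to_a = dict(zip(pairs[col_b], pairs[col_a]))

    rows = []
    for calls, other, mapping in (
        (calls_a, calls_b, a_to_b),
        (calls_b, calls_a, b_to_a),
    ):
        imprinted = calls.index[calls["category"].isin(IMPRINTED_CATEGORIES)]
        for fid in imprinted:
            partner = mapping.get(fid)
            if partner is None or partner not in other.index:
                status = "unique_to_one_genome"
            elif other.loc[partner, "category"] == calls.loc[fid, "category"]:
                status = "shared_imprinted"
            else:
                status = "assessable_not_shared"
            rows.append(
                {
                    "feature_id": fid,
                    "genome": calls.loc[fid, "genome"],
                    "category": calls.loc[fid, "category"],
                    "counterpart": partner,
                    "status": status,
                }
            )
    return pd.DataFrame(rows, columns=["feature_id", "genome", "category", "counterpart", "status"])


def _signed_gap(te: FeatureAnnotation, gene: FeatureAnnotation) -> int:
    """Gap in bp, signed relative to gene orientation; 0 on overlap.

    Positive when the TE lies downstream of the gene in the gene's
    orientation (the bedtools closest ``-D b`` analog), negative upstream.
    """
    te_start, te_end = te.span
    g_start, g_end = gene.span
    if te_start < g_end and g_start < te_end:
        return 0
    if te_start >= g_end:  # TE to the right of the gene
        gap = te_start - g_end
        after = True
    else:
        gap = g_start - te_end
        after = False
    downstream = after if gene.strand != "-" else not after
    return gap if downstream else -gap


def nearest_gene(
    tes: list[FeatureAnnotation],
    genes: list[FeatureAnnotation],
    gene_categories: dict[str, str] | None = None,
) -> list[NearestGeneResult]:
    """Closest gene for every TE, with orientation-signed distance.

    Ties on |distance| break toward the smaller gene start, then lexical
    gene id. TEs on chromosomes without genes are skipped with a log
    record.
    """
    gene_categories = gene_categories or {}
    by_chrom: dict[str, list[FeatureAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    results = []
    for te in tes:
        candidates = by_chrom.get(te.chrom)
        if not candidates:
            logger.info("no genes on %s; skipping TE %s", te.chrom, te.feature_id)
            continue
        best = min(
            candidates,
            key=lambda g: (abs(_signed_gap(te, g)), g.span[0], g.feature_id),
        )
        results.append(
            NearestGeneResult(
                te.feature_id,
                best.feature_id,
                _signed_gap(te, best),
                gene_categories.get(best.feature_id),
            )
        )
    return results


def binomial_enrichment(
    k_hits: int, n_trials: int, p_expected: float
) -> tuple[float, float]:
    """Fold enrichment and exact binomial upper-tail p-value P(X >= k)."""
    if not 0 <= k_hits <= n_trials:
        raise ValueError("need 0 <= k_hits <= n_trials")
    if not 0 < p_expected < 1:
        raise ValueError("p_expected must lie strictly between 0 and 1")
    fold = (k_hits / n_trials) / p_expected if n_trials else 0.0
    pval = stats.binomtest(k_hits, n_trials, p_expected, alternative="greater").pvalue
    return fold, float(pval)


def categorical_enrichment(
    table: np.ndarray | pd.DataFrame, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value for a 2 x k contingency table.

    No continuity correction by default (configurable for 2 x 2 tables).
    """
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table must hold non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def two_sample_mean_test(x, y) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances).

    Degenerate case: both samples constant with equal means gives (0, 1);
    both constant with different means is an error (undefined variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
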