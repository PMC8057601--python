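"""Dosage-aware imprinting test and MEG/PEG/matTE classification.

In endosperm the maternal genome is present in two copies and the paternal
in one, so the null for any biparentally expressed feature is a two-fold
(log2 = 1) maternal excess across reciprocal crosses — not equality. Each
feature is therefore tested with a threshold Wald test against
H0: |lfc| <= 1 on a negative-binomial two-group model (libraries where the
feature's genome was inherited maternally vs paternally), and significant
features are further gated on the RER statistic (> 0.9 maternal, < 0.1
paternal) to keep only strong imprinting.

The model is deliberately simple: median-of-ratios size factors, a
method-of-moments NB dispersion per feature, the log fold change as the
difference of log2 group means of normalized counts (with a half-count
offset so all-zero groups stay finite), and a delta-method standard error.
No empirical-Bayes shrinkage, Cox-Reid dispersion, or outlier handling is
attempted; the test's operating characteristics (type-I control at exact
2:1 dosage, power on monoallelic features) are what is validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "DosageTestResult",
    "ImprintThresholds",
    "estimate_size_factors",
    "estimate_dispersion",
    "threshold_wald_test",
    "bh_adjust",
    "dosage_test",
    "classify_imprinting",
]

DISPERSION_FLOOR = 1e-8
LOG2 = np.log(2.0)


@dataclass
class DosageTestResult:
    feature_id: str
    genome: str
    lfc: float
    se: float
    p: float
    padj: float
    direction: str  # "maternal" | "paternal"


@dataclass
class ImprintThresholds:
    """Cutoffs for the final imprinting call.

    All inequalities are strict, so a feature sitting exactly on a cutoff
    (padj = alpha, rer = rer_meg or rer_peg) is not called imprinted.
    """

    lfc_threshold: float = 1.0
    alpha: float = 0.05
    rer_meg: float = 0.9
    rer_peg: float = 0.1
    min_total_count: int = 10


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For features with nonzero counts in every library, each library's
    factor is the median of count / geometric-row-mean. When no feature is
    everywhere-nonzero the estimator falls back to library-total scaling
    (normalized to geometric mean 1) with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    everywhere = (mat > 0).all(axis=1)
    if everywhere.any():
        sub = mat[everywhere]
        log_geo = np.mean(np.log(sub), axis=1)
        ratios = sub / np.exp(log_geo)[:, None]
        factors = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no feature with nonzero counts in all libraries; "
            "falling back to library-total size factors"
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).all():
            raise ValueError("cannot estimate size factors: all libraries empty")
        nz = totals > 0
        factors = np.ones_like(totals)
        factors[nz] = totals[nz] / np.exp(np.mean(np.log(totals[nz])))
    return pd.Series(factors, index=counts.columns)


def estimate_dispersion(
    feature_counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray | None = None,
) -> float:
    """Method-of-moments NB dispersion for one feature.

    Counts are normalized by the size factors; within each group (or the
    whole vector if ``groups`` is None) the dispersion solves
    var = mean * E[1/s] + alpha * mean^2, and group estimates are pooled
    weighted by their degrees of freedom. Floored at 1e-8. Returns NaN for
    an all-zero feature.
    """
    y = np.asarray(feature_counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    if y.sum() == 0:
        return np.nan
    if groups is None:
        groups = np.zeros(len(y), dtype=int)
    est_num = est_den = 0.0
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            continue
        x = y[mask] / s[mask]
        m = x.mean()
        if m == 0:
            continue
        v = x.var(ddof=1)
        shot = m * np.mean(1.0 / s[mask])  # Poisson part of Var(K/s)
        alpha_g = (v - shot) / m**2
        w = mask.sum() - 1
        est_num += w * alpha_g
        est_den += w
    if est_den == 0:
        return DISPERSION_FLOOR
    return max(est_num / est_den, DISPERSION_FLOOR)


def threshold_wald_test(lfc: float, se: float, theta: float = 1.0) -> float:
    """Two-sided threshold Wald p-value for H0: |lfc| <= theta.

    W = (|lfc| - theta) / se; p = min(1, 2 * P(Z > W)). For |lfc| at or
    below the threshold the p-value caps at 1.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    w = (abs(lfc) - theta) / se
    return float(min(1.0, 2.0 * stats.norm.sf(w)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(
    x: np.ndarray, inv_s_mean: float, alpha: float, n: int
) -> tuple[float, float]:
    """Mean of normalized counts and the variance of that mean under NB."""
    m = x.mean()
    var_mean = (m * inv_s_mean + alpha * m**2) / n
    return m, var_mean


def dosage_test(
    table: CountTable,
    lfc_threshold: float = 1.0,
    min_total_count: int = 10,
    offset: float = 0.5,
) -> pd.DataFrame:
    """Test every feature for expression beyond the 2:1 dosage expectation.

    Per feature: maternal-inheritance libraries (feature's genome is the
    mother) vs paternal-inheritance libraries; lfc is the difference of
    log2 mean normalized counts (plus ``offset`` to keep all-zero groups
    finite), the SE comes from the NB delta method, and the p-value from
    :func:`threshold_wald_test`. Features with total count below
    ``min_total_count`` are excluded before testing and before BH
    adjustment. Each genome's allele is tested independently.
    """
    sf = estimate_size_factors(table.counts)
    sf_arr = sf.to_numpy()
    genomes = table.features["genome"]
    sample_ids = list(table.counts.columns)
    mothers = {s.library_id: s.mother for s in table.samples}
    fathers = {s.library_id: s.father for s in table.samples}

    rows = []
    mat = table.counts.to_numpy(dtype=float)
    col_of = {lib: j for j, lib in enumerate(sample_ids)}
    for g in genomes.unique():
        mat_idx = np.array([col_of[l] for l in sample_ids if mothers[l] == g], dtype=int)
        pat_idx = np.array([col_of[l] for l in sample_ids if fathers[l] == g], dtype=int)
        if len(mat_idx) == 0 or len(pat_idx) == 0:
            continue
        group_vec = np.full(len(sample_ids), -1)
        group_vec[mat_idx] = 0
        group_vec[pat_idx] = 1
        used = np.concatenate([mat_idx, pat_idx])
        inv_m = float(np.mean(1.0 / sf_arr[mat_idx]))
        inv_p = float(np.mean(1.0 / sf_arr[pat_idx]))
        feat_rows = np.nonzero((genomes == g).to_numpy())[0]
        for i in feat_rows:
            y = mat[i]
            if y[used].sum() < min_total_count:
                continue
            alpha = estimate_dispersion(y[used], sf_arr[used], group_vec[used])
            if np.isnan(alpha):
                continue
            xm = y[mat_idx] / sf_arr[mat_idx]
            xp = y[pat_idx] / sf_arr[pat_idx]
            mm, var_mm = _group_stats(xm, inv_m, alpha, len(mat_idx))
            mp, var_mp = _group_stats(xp, inv_p, alpha, len(pat_idx))
            lfc = float(np.log2(mm + offset) - np.log2(mp + offset))
            se2 = var_mm / (mm + offset) ** 2 + var_mp / (mp + offset) ** 2
            se = float(np.sqrt(se2) / LOG2)
            se = max(se, 1e-8)
            p = threshold_wald_test(lfc, se, lfc_threshold)
            rows.append(
                {
                    "feature_id": table.counts.index[i],
                    "genome": g,
                    "kind": table.features.iloc[i]["kind"],
                    "base_mean": float((y[used] / sf_arr[used]).mean()),
                    "lfc": lfc,
                    "se": se,
                    "p": p,
                    "direction": "maternal" if lfc > 0 else "paternal",
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["genome", "kind", "base_mean", "lfc", "se", "p", "padj", "direction"]
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def classify_imprinting(
    test: pd.DataFrame,
    rer: pd.DataFrame,
    thresholds: ImprintThresholds | None = None,
    pericarp_flagged: set[str] | None = None,
    paternal_te_excluded: bool = False,
) -> pd.DataFrame:
    """Final per-feature imprinting categories for one contrast.

    MEG / matTE: padj < alpha, maternal direction, RER > rer_meg.
    PEG / patTE: padj < alpha, paternal direction, RER < rer_peg.
    Maternal gene calls whose feature is pericarp-flagged become
    ``excluded_pericarp``; TE paternal calls in a contrast flagged
    unreliable become ``excluded_paternalTE_contrast``. Everything else is
    ``not_imprinted``.
    """
    th = thresholds or ImprintThresholds()
    pericarp_flagged = pericarp_flagged or set()

    out = rer.copy()
    merged = out.join(test[["lfc", "se", "p", "padj", "direction"]], how="left")
    categories = []
    for fid, row in merged.iterrows():
        cat = "not_imprinted"
        padj = row.get("padj", np.nan)
        r = row["rer"]
        if fid in test.index and np.isnan(r):
            logger.warning("feature %s tested but has undefined RER; not imprinted", fid)
        elif not np.isnan(padj) and padj < th.alpha:
            if row["direction"] == "maternal" and r > th.rer_meg:
                if row["kind"] == "gene" and fid in pericarp_flagged:
                    cat = "excluded_pericarp"
                else:
                    cat = "MEG" if row["kind"] == "gene" else "matTE"
            elif row["direction"] == "paternal" and r < th.rer_peg:
                if row["kind"] == "TE" and paternal_te_excluded:
                    cat = "excluded_paternalTE_contrast"
                else:
                    cat = "PEG" if row["kind"] == "gene" else "patTE"
        categories.append(cat)
    merged["category"] = categories
    return merged
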