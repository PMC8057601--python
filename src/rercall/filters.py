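"""Tissue-dynamics filters.

Endosperm dissections inevitably carry some maternal seed coat (pericarp),
and pericarp expression can masquerade as maternal imprinting. Features
whose mean expression in pericarp libraries exceeds twice the endosperm
mean are therefore flagged and excluded from maternal (MEG) calls, with
flags propagated to corresponding genes in the other genomes via the
ortholog map. A second, descriptive classification marks features as
endosperm-preferred when endosperm + whole-seed libraries carry more than
60% of the feature's total expression across a multi-tissue atlas. Both
rules are ratio-based and scale-free.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "pericarp_flag",
    "propagate_flags",
    "endosperm_preferred",
    "tissue_flags",
]

TISSUE_CLASSES = {"endosperm", "seed", "pericarp", "other"}


def _class_columns(tissue_classes: pd.Series, wanted: set[str]) -> list:
    unknown = set(tissue_classes.unique()) - TISSUE_CLASSES
    if unknown:
        raise ValueError(f"unknown tissue classes: {sorted(unknown)}")
    return list(tissue_classes.index[tissue_classes.isin(wanted)])


def pericarp_flag(
    expression: pd.DataFrame,
    tissue_classes: pd.Series,
    fold: float = 2.0,
) -> pd.Series:
    """True where mean pericarp expression exceeds ``fold`` x endosperm mean.

    Strict inequality: a feature exactly at the fold boundary is kept.
    ``tissue_classes`` maps library -> class and must cover at least one
    endosperm and one pericarp library.
    """
    missing = set(expression.columns) - set(tissue_classes.index)
    if missing:
        raise ValueError(f"libraries without a tissue class: {sorted(missing)}")
    peri = _class_columns(tissue_classes, {"pericarp"})
    endo = _class_columns(tissue_classes, {"endosperm"})
    if not peri or not endo:
        raise ValueError("need at least one pericarp and one endosperm library")
    peri_mean = expression[peri].mean(axis=1)
    endo_mean = expression[endo].mean(axis=1)
    return peri_mean > fold * endo_mean


def propagate_flags(
    flags: pd.Series,
    ortholog_map: pd.DataFrame,
    anchor_col: str,
    target_col: str,
) -> set[str]:
    """Carry flags from anchor-genome genes to their orthologs.

    Returns the set of flagged target-genome gene ids. Anchor genes absent
    from the map, and unflagged genes, propagate nothing.
    """
    flagged_anchors = set(flags.index[flags])
    sub = ortholog_map[[anchor_col, target_col]].dropna()
    return set(sub.loc[sub[anchor_col].isin(flagged_anchors), target_col])


def endosperm_preferred(
    expression: pd.DataFrame,
    tissue_classes: pd.Series,
    fraction: float = 0.6,
) -> pd.Series:
    """True where endosperm + seed libraries carry > ``fraction`` of the
    feature's summed expression (strict; zero-total features are False)."""
    missing = set(expression.columns) - set(tissue_classes.index)
    if missing:
        raise ValueError(f"libraries without a tissue class: {sorted(missing)}")
    endo_seed = _class_columns(tissue_classes, {"endosperm", "seed"})
    focal = expression[endo_seed].sum(axis=1)
    total = expression.sum(axis=1)
    return (total > 0) & (focal > fraction * total)


def tissue_flags(
    expression: pd.DataFrame,
    tissue_classes: pd.Series,
    fold: float = 2.0,
    fraction: float = 0.6,
) -> pd.DataFrame:
    """Both flags as one table (feature_id, pericarp_flag, endosperm_preferred)."""
    return pd.DataFrame(
        {
            "pericarp_flag": pericarp_flag(expression, tissue_classes, fold),
            "endosperm_preferred": endosperm_preferred(
                expression, tissue_classes, fraction
            ),
        }
    )
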