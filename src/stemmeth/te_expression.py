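"""Descriptive summaries of transposable-element expression dynamics.

This module consumes a TPM-like abundance matrix with paired stem /
non-stem samples per developmental stage and computes: per-feature
log2 fold-changes, TE-family aggregation (summing member abundances),
counts of families beyond a fold threshold per stage, distribution-shift
tests between feature classes (two-sided unpaired Wilcoxon rank-sum), and
the small-offset log transform used to display zero-containing values on a
log scale. It deliberately does not re-derive differential-expression
significance from counts; it summarizes a supplied matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


def log2fc(matrix: ExpressionMatrix, stage: str, pseudocount: float = 1.0) -> pd.Series:
    """Per-feature log2((stem + pc) / (nonstem + pc)) at one stage.

    With multiple replicate columns per fraction, replicate means are
    taken first. The pseudocount keeps every value finite.
    """
    stem_cols = matrix.columns_for(stage, "stem")
    nonstem_cols = matrix.columns_for(stage, "nonstem")
    if not stem_cols or not nonstem_cols:
        raise ValueError(f"stage {stage!r} lacks a stem or non-stem sample")
    stem = matrix.values[stem_cols].mean(axis=1)
    nonstem = matrix.values[nonstem_cols].mean(axis=1)
    out = np.log2(stem + pseudocount) - np.log2(nonstem + pseudocount)
    out.name = f"log2fc_{stage}"
    return out


def family_aggregate(matrix: ExpressionMatrix, level: str = "family") -> ExpressionMatrix:
    """Aggregate TE features to families (or superfamilies) by summing.

    Non-TE features are dropped; a TE without a family label goes to
    "Unknown" with a warning. The per-sample TE total is conserved.
    """
    if level not in ("family", "superfamily"):
        raise ValueError("level must be 'family' or 'superfamily'")
    is_te = matrix.feature_meta["class"] == "TE"
    fam = matrix.feature_meta.loc[is_te, level].copy()
    empty = (fam == "") | fam.isna()
    if empty.any():
        logger.warning("%d TE features lack a %s label; assigned to 'Unknown'", int(empty.sum()), level)
        fam[empty] = "Unknown"
    values = matrix.values[is_te].groupby(fam).sum()
    values.index.name = level
    feature_meta = pd.DataFrame(
        {
            "class": "TE",
            "family": values.index if level == "family" else "",
            "superfamily": (
                matrix.feature_meta.loc[is_te].groupby(fam)["superfamily"].first()
                if level == "family"
                else values.index
            ),
        },
        index=values.index,
    )
    return ExpressionMatrix(values=values, feature_meta=feature_meta, sample_meta=matrix.sample_meta)


def count_fold_families(
    family_lfc: pd.DataFrame, threshold_lfc: float = 1.0
) -> pd.DataFrame:
    """Per-stage counts of families at or beyond a fold threshold.

    ``family_lfc`` is families x stages of log2 fold-changes (stem over
    non-stem). The boundary counts: lfc >= threshold is "up",
    lfc <= -threshold is "down" (threshold 1 means at least 2x). Families
    with an undefined lfc in a stage are excluded from that stage's counts
    and reported.
    """
    rows = []
    for stage in family_lfc.columns:
        v = family_lfc[stage]
        n_undef = int(v.isna().sum())
        if n_undef:
            logger.warning("stage %s: %d families with undefined log2fc excluded", stage, n_undef)
        v = v.dropna()
        rows.append(
            {
                "stage": stage,
                "up": int((v >= threshold_lfc).sum()),
                "down": int((v <= -threshold_lfc).sum()),
                "n_excluded": n_undef,
            }
        )
    return pd.DataFrame(rows).set_index("stage")


def class_shift_test(values_a, values_b) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p for a shift between classes.

    Exact enumeration when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def log_offset_transform(values, offset: float = 1.0e-6):
    """log10(values + offset): finite for zeros, monotone.

    The default offset of 1e-6 follows the convention of adding a value a
    factor 10 below the smallest observed non-zero abundance so that zero
    measurements remain displayable on a log scale.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("values must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.log10(arr + offset)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
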