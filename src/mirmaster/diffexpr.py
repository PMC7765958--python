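"""Differential expression, multiple-testing correction and signatures.

Genes: two-sided two-sample t-test (Welch by default) on log2 values per
contrast, Benjamini-Hochberg FDR across the contrast's features; the
phenotype signature splits the FDR < 0.05 calls into an "up" set
(log2FC > 0) and a "down" set (log2FC < 0).

miRNAs: same test, but the DE call is |log2FC| > 0.25 AND raw p < 0.01
(strict inequalities), the first filtering step of the master-regulator
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import Signature, parse_contrast

DE_COLUMNS = ["feature_id", "contrast", "log2fc", "p_value", "adj_p", "direction"]


@dataclass(frozen=True)
class MirnaDECriteria:
    """Thresholds of the miRNA differential-expression call."""

    fc_threshold: float = 0.25  # on |log2fc|, strict
    p_threshold: float = 0.01  # raw p, strict

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns; tied values
    within a column receive the mean of the reference values at the tied
    ranks.  Feature and sample ids are preserved.
    """
    if matrix.shape[1] == 1:
        warnings.warn("single-sample matrix: quantile normalization is the identity")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains missing or non-finite values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference values over runs of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        groups = np.split(np.arange(len(col)), boundaries)
        for grp in groups:
            if len(grp) > 1:
                ranked[order[grp]] = reference[grp].mean()
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Step-up FDR adjustment; ``method`` is ``"BH"`` or ``"BY"``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def _group_matrices(
    matrix: pd.DataFrame, annotation: pd.Series, contrast: str
) -> tuple[np.ndarray, np.ndarray]:
    g1, g2 = parse_contrast(contrast)
    conditions = set(annotation)
    for g in (g1, g2):
        if g not in conditions:
            raise ValueError(f"condition {g!r} not present in the annotation")
    s1 = annotation.index[annotation == g1]
    s2 = annotation.index[annotation == g2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need at least 2 samples per group")
    return matrix[s1].to_numpy(dtype=float), matrix[s2].to_numpy(dtype=float)


def differential_expression(
    matrix: pd.DataFrame,
    annotation: pd.Series,
    contrast: str,
    method: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature t-test and BH adjustment for one contrast.

    log2fc = mean(group1) - mean(group2) with group1 the first-named
    condition.  Degenerate features (zero variance in both groups, equal
    means) get p = 1.  Returns a table with one row per feature and a
    ``direction`` column (up/down/ns) based on ``adj_p < alpha``.
    """
    a, b = _group_matrices(matrix, annotation, contrast)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (near-constant) features are handled below via p = 1
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=(method == "pooled"))
    p = np.where(np.isnan(p), 1.0, p)
    adj = adjust_pvalues(p, "BH")
    direction = np.where(adj < alpha, np.where(log2fc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {
            "feature_id": matrix.index,
            "contrast": contrast,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj,
            "direction": direction,
        }
    ).reset_index(drop=True)


def mirna_differential_expression(
    matrix: pd.DataFrame,
    annotation: pd.Series,
    contrast: str,
    criteria: MirnaDECriteria = MirnaDECriteria(),
    method: str = "welch",
) -> pd.DataFrame:
    """miRNA DE call: |log2fc| > fc_threshold AND raw p < p_threshold."""
    table = differential_expression(matrix, annotation, contrast, method=method)
    de = (np.abs(table["log2fc"]) > criteria.fc_threshold) & (
        table["p_value"] < criteria.p_threshold
    )
    table["direction"] = np.where(de, np.where(table["log2fc"] > 0, "up", "down"), "ns")
    return table


def build_signature(records: pd.DataFrame, threshold: float = 0.05) -> Signature:
    """Split the ``adj_p < threshold`` features into up/down sets."""
    contrasts = records["contrast"].unique()
    if len(contrasts) != 1:
        raise ValueError("signature must be built from a single contrast")
    sig = records[records["adj_p"] < threshold]
    up = frozenset(sig.loc[sig["log2fc"] > 0, "feature_id"])
    down = frozenset(sig.loc[sig["log2fc"] < 0, "feature_id"])
    return Signature(contrast=str(contrasts[0]), up=up, down=down)


def de_mirna_sets(table: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Up/down miRNA id sets from a miRNA DE table."""
    up = set(table.loc[table["direction"] == "up", "feature_id"])
    down = set(table.loc[table["direction"] == "down", "feature_id"])
    return up, down
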