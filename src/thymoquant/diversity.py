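"""Repertoire clonality and tissue-restricted antigen (TRA) statistics.

The Gini index used throughout is the population form
``G = sum_ij |x_i - x_j| / (2 n sum x)``, computed by the O(n log n) sorted
expression, so perfect equality gives 0 and full concentration in one of n
elements gives (n - 1)/n. Repertoire Gini is computed on read counts
(``duplicate_count``) aggregated by CDR3 amino-acid sequence per sample.

A TRA is a gene whose mean expression across tissues has Gini > 0.8 and
whose maximally expressing tissue exceeds 100 TPM (strict inequalities).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .core_stats import bh_adjust, mann_whitney_u

__all__ = [
    "gini",
    "repertoire_gini",
    "segment_usage",
    "segment_usage_test",
    "pair_fold_change",
    "call_tras",
]

logger = logging.getLogger(__name__)

_FAMILY_COLS = {"V": ["v_call"], "J": ["j_call"], "VJ": ["v_call", "j_call"]}


def gini(values: Sequence[float]) -> float:
    """Population Gini index of non-negative values (not all zero)."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty input")
    if np.any(x < 0):
        raise ValueError("negative values are not allowed")
    total = x.sum()
    if total <= 0:
        raise ValueError("values sum to zero; Gini undefined")
    n = x.size
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * total))


def repertoire_gini(
    table: pd.DataFrame,
    level: str = "junction_aa",
    sample_col: str = "sample_id",
    count_col: str = "duplicate_count",
) -> pd.Series:
    """Per-sample Gini of clone sizes.

    ``level="junction_aa"`` aggregates read counts by CDR3 amino-acid
    sequence; ``level="clonotype"`` by the full (v_call, j_call, junction_aa)
    key. Samples with no reads are skipped with a warning.
    """
    if level == "junction_aa":
        keys = ["junction_aa"]
    elif level == "clonotype":
        keys = ["v_call", "j_call", "junction_aa"]
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    out: dict[str, float] = {}
    for sample, sub in table.groupby(sample_col, sort=True):
        sizes = sub.groupby(keys, sort=False)[count_col].sum().to_numpy()
        if sizes.size == 0 or sizes.sum() <= 0:
            logger.warning("sample %s has no reads; skipped", sample)
            continue
        out[sample] = gini(sizes)
    return pd.Series(out, name=f"gini_{level}")


def segment_usage(
    table: pd.DataFrame,
    family: str = "J",
    sample_col: str = "sample_id",
    count_col: str = "duplicate_count",
    weight: str = "reads",
) -> pd.DataFrame:
    """Samples x segments matrix of usage fractions.

    Read-weighted by default (fraction of reads per segment); ``weight=
    "clones"`` counts each clonotype once. Rows sum to 1.
    """
    if family not in _FAMILY_COLS:
        raise ValueError(f"family must be one of {sorted(_FAMILY_COLS)}, got {family!r}")
    cols = _FAMILY_COLS[family]
    work = table.copy()
    if len(cols) == 2:
        work["_segment"] = work[cols[0]].astype(str) + "|" + work[cols[1]].astype(str)
    else:
        work["_segment"] = work[cols[0]].astype(str)
    w = work[count_col] if weight == "reads" else pd.Series(1, index=work.index)
    work = work.assign(_w=w)
    usage = work.pivot_table(
        index=sample_col, columns="_segment", values="_w", aggfunc="sum", fill_value=0.0
    ).astype(float)
    totals = usage.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("a sample has zero total weight")
    return usage.div(totals, axis=0)


def segment_usage_test(
    table: pd.DataFrame,
    family: str = "J",
    group_col: str = "group",
    sample_col: str = "sample_id",
    count_col: str = "duplicate_count",
    weight: str = "reads",
) -> pd.DataFrame:
    """Per-segment group comparison of usage fractions.

    Two-sided Mann--Whitney U on per-sample fractions between the two
    groups, Benjamini--Hochberg across segments. Requires >= 2 samples per
    group.
    """
    groups = table.groupby(sample_col)[group_col].agg(lambda s: s.iloc[0])
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    usage = segment_usage(table, family=family, sample_col=sample_col,
                          count_col=count_col, weight=weight)
    groups = groups.loc[usage.index]
    in_a = (groups == labels[0]).to_numpy()
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    records = []
    for segment in usage.columns:
        frac = usage[segment].to_numpy()
        u, p = mann_whitney_u(frac[in_a], frac[~in_a])
        records.append(
            {
                "segment": segment,
                f"mean_{labels[0]}": float(frac[in_a].mean()),
                f"mean_{labels[1]}": float(frac[~in_a].mean()),
                "U": u,
                "p": p,
            }
        )
    out = pd.DataFrame(records)
    out["q"] = bh_adjust(out["p"].to_list()).adjusted
    return out.sort_values("q", kind="stable").reset_index(drop=True)


def pair_fold_change(
    table: pd.DataFrame,
    v: str,
    j: str,
    group_a: str,
    group_b: str,
    group_col: str = "group",
    count_col: str = "duplicate_count",
) -> float:
    """Fold change of a V-J pair's pooled read fraction between groups.

    ``(fraction of reads on (v, j) in group_a) / (fraction in group_b)``;
    returns ``inf`` (flagged in the log) when the pair is absent from
    group_b but present in group_a, and raises if absent from both.
    """

    def fraction(group: str) -> float:
        sub = table[table[group_col] == group]
        total = sub[count_col].sum()
        if total <= 0:
            raise ValueError(f"group {group!r} has no reads")
        hit = sub[(sub["v_call"] == v) & (sub["j_call"] == j)][count_col].sum()
        return float(hit) / float(total)

    fa, fb = fraction(group_a), fraction(group_b)
    if fa == 0.0 and fb == 0.0:
        raise ValueError(f"pair ({v}, {j}) absent from both groups; fold change undefined")
    if fb == 0.0:
        logger.warning("pair (%s, %s) absent from group %s; fold change infinite", v, j, group_b)
        return math.inf
    return fa / fb


def call_tras(
    expression: pd.DataFrame,
    gini_threshold: float = 0.8,
    tpm_threshold: float = 100.0,
) -> pd.DataFrame:
    """Tissue-restricted antigen calls from a genes x tissues mean-TPM table.

    Per gene: Gini across tissue means, maximally expressing tissue and its
    TPM; ``is_tra`` iff Gini > gini_threshold and max TPM > tpm_threshold
    (both strict). Genes with all-zero expression get a missing Gini and are
    never called.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two tissues")
    if (expression.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    records = []
    for gene, row in expression.iterrows():
        vals = row.to_numpy(dtype=float)
        max_idx = int(np.argmax(vals))
        max_tpm = float(vals[max_idx])
        if vals.sum() <= 0:
            g = math.nan
            is_tra = False
        else:
            g = gini(vals)
            is_tra = (g > gini_threshold) and (max_tpm > tpm_threshold)
        records.append(
            {
                "gene": gene,
                "gini": g,
                "max_tissue": expression.columns[max_idx],
                "max_tpm": max_tpm,
                "is_tra": is_tra,
            }
        )
    return pd.DataFrame(records)
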