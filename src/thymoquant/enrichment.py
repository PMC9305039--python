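"""Gene-set scoring against expression-matched controls, with cluster tests.

The score of a cell is the mean expression of the set genes minus the mean
of a pooled control set: genes are ranked by average expression over all
cells, cut into ``n_bins`` equal-size bins, and each set gene contributes
``ctrl_per_gene`` control genes sampled (without replacement, set genes
excluded) from its own bin, so controls match the set's expression profile.
Cluster enrichment is a two-sided Mann--Whitney U of a cluster's scores
against all other cells, Benjamini--Hochberg corrected across clusters.
"""

from __future__ import annotations

import logging
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .core_stats import bh_adjust, mann_whitney_u

__all__ = ["score_gene_set", "cluster_score_test"]

logger = logging.getLogger(__name__)


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def score_gene_set(
    adata: ad.AnnData,
    gene_set: Sequence[str],
    n_bins: int = 25,
    ctrl_per_gene: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell score of a gene set against binned expression-matched controls.

    Set genes absent from the matrix are dropped with a warning; an empty
    remaining set, or a set that exhausts the control pool, is an error.
    Deterministic for a fixed seed; within-bin gene ranking ties are broken
    by gene-id order.
    """
    genes = list(map(str, adata.var_names))
    present = [g for g in gene_set if g in set(genes)]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        logger.warning("%d gene(s) of the set absent from the matrix: %s",
                       len(missing), ", ".join(missing[:5]))
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    X = _dense(adata)
    mean_expr = X.mean(axis=0)

    # rank by mean expression, ties by gene id, then cut into equal-size bins
    order = sorted(range(len(genes)), key=lambda i: (mean_expr[i], genes[i]))
    bin_of = np.empty(len(genes), dtype=int)
    for b, chunk in enumerate(np.array_split(np.asarray(order), n_bins)):
        bin_of[chunk] = b

    set_idx = sorted(genes.index(g) for g in set(present))
    set_mask = np.zeros(len(genes), dtype=bool)
    set_mask[set_idx] = True

    rng = np.random.default_rng(seed)
    control: set[int] = set()
    for gi in set_idx:
        pool = np.flatnonzero((bin_of == bin_of[gi]) & ~set_mask)
        if pool.size == 0:
            continue
        take = min(ctrl_per_gene, pool.size)
        control.update(rng.choice(pool, size=take, replace=False).tolist())
    if not control:
        raise ValueError(
            "control pool is empty (the gene set covers its expression bins entirely)"
        )
    ctrl_idx = sorted(control)
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def cluster_score_test(
    scores: Sequence[float], labels: Sequence[str]
) -> pd.DataFrame:
    """Cluster-vs-rest Mann--Whitney tests of per-cell scores.

    Returns one row per cluster with the cluster mean score, U, two-sided p,
    BH q across clusters, and the direction (+1 enriched, -1 depleted).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels differ in length")
    clusters = sorted(pd.unique(labels).tolist())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    records = []
    for cluster in clusters:
        mask = labels == cluster
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"cluster {cluster!r} or its complement has < 2 cells")
        u, p = mann_whitney_u(scores[mask], scores[~mask])
        diff = float(scores[mask].mean() - scores[~mask].mean())
        records.append(
            {
                "cluster": cluster,
                "n_cells": int(mask.sum()),
                "mean_score": float(scores[mask].mean()),
                "U": u,
                "p": p,
                "direction": 1 if diff >= 0 else -1,
            }
        )
    out = pd.DataFrame(records)
    out["q"] = bh_adjust(out["p"].to_list()).adjusted
    return out
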