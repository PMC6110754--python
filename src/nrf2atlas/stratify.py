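"""Cohort stratification with the selected activation signature.

Ward clustering of all samples on the signature genes, cut into three
groups; designation follows the tissue and expression structure: G1 is the
cluster richest in normal tissue, and of the remaining two tumor clusters
G2 (NRF2-active) is the one with the higher mean signature expression, G3
(NRF2-inactive) the other. Mutant enrichment between G2 and G3 is a
one-sided Fisher exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class StratificationResult:
    """Per-sample cluster and G1/G2/G3 group assignment plus designation
    metadata (normal fraction and mean signature expression per cluster)."""

    assignment: pd.DataFrame  # columns: sample, cluster, group
    normal_fraction: dict[int, float]
    mean_signature: dict[int, float]
    group_of_cluster: dict[int, str] = field(default_factory=dict)


def ward_cluster(transformed: pd.DataFrame, k: int = 3) -> pd.Series:
    """Ward-linkage clustering of samples (columns) on Euclidean distances,
    dendrogram cut into ``k`` clusters. Deterministic; the partition is
    invariant to column order (labels may permute)."""
    if transformed.shape[1] < k:
        raise ValueError(f"need >= {k} samples, got {transformed.shape[1]}")
    if k == 1:
        return pd.Series(1, index=transformed.columns, name="cluster")
    pts = transformed.to_numpy().T
    labels = fcluster(linkage(pts, method="ward"), t=k, criterion="maxclust")
    return pd.Series(labels, index=transformed.columns, name="cluster")


def designate_groups(
    clusters: pd.Series,
    is_normal: pd.Series,
    signature_expression: pd.DataFrame,
    up_genes: list[str] | None = None,
) -> StratificationResult:
    """Name the three clusters G1 (normal), G2 (active), G3 (inactive).

    G1 is the cluster with the highest fraction of normal-tissue samples.
    Of the two others, G2 has the higher mean signature expression and G3
    the lower; mean signature expression uses the up-regulated signature
    genes when ``up_genes`` is given, all signature genes otherwise. Ties
    are broken deterministically (larger cluster -> G3) with a warning.
    """
    ids = sorted(clusters.unique())
    if len(ids) != 3:
        raise ValueError(f"expected 3 clusters, got {len(ids)}")
    is_normal = is_normal.reindex(clusters.index).astype(bool)
    expr = signature_expression.loc[up_genes] if up_genes else signature_expression
    mean_sig = {
        c: float(expr.loc[:, clusters.index[clusters == c]].to_numpy().mean())
        for c in ids
    }
    norm_frac = {
        c: float(is_normal[clusters == c].mean()) for c in ids
    }
    top = max(norm_frac.values())
    tied = [c for c in ids if norm_frac[c] == top]
    if len(tied) > 1:
        warnings.warn("clusters tied on normal fraction; picking the smaller id", stacklevel=2)
    g1 = min(tied)
    rest = [c for c in ids if c != g1]
    if mean_sig[rest[0]] == mean_sig[rest[1]]:
        warnings.warn("clusters tied on mean signature expression; larger cluster -> G3",
                      stacklevel=2)
        sizes = {c: int((clusters == c).sum()) for c in rest}
        g3 = max(rest, key=lambda c: (sizes[c], c))
        g2 = next(c for c in rest if c != g3)
    else:
        g2 = max(rest, key=lambda c: mean_sig[c])
        g3 = next(c for c in rest if c != g2)
    group_of = {g1: "G1", g2: "G2", g3: "G3"}
    assignment = pd.DataFrame({
        "sample": clusters.index,
        "cluster": clusters.to_numpy(),
        "group": [group_of[c] for c in clusters],
    })
    return StratificationResult(assignment, norm_frac, mean_sig, group_of)


def group_enrichment(
    assignment: pd.DataFrame,
    mutant_cases: set[str],
) -> tuple[float, np.ndarray]:
    """One-sided Fisher exact test for mutant over-representation in G2
    relative to G3.

    Returns (p, table) where table is the 2x2 array
    [[G2 mutant, G2 non-mutant], [G3 mutant, G3 non-mutant]]. An empty
    margin gives p = 1 with a warning.
    """
    g2 = assignment.loc[assignment["group"] == "G2", "sample"]
    g3 = assignment.loc[assignment["group"] == "G3", "sample"]
    if len(g2) == 0 or len(g3) == 0:
        raise ValueError("G2 and G3 must both be non-empty")
    tab = np.array([
        [int(g2.isin(mutant_cases).sum()), int((~g2.isin(mutant_cases)).sum())],
        [int(g3.isin(mutant_cases).sum()), int((~g3.isin(mutant_cases)).sum())],
    ])
    if (tab.sum(axis=0) == 0).any():
        warnings.warn("empty margin in the 2x2 table; p = 1", stacklevel=2)
        return 1.0, tab
    return float(stats.fisher_exact(tab, alternative="greater")[1]), tab
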