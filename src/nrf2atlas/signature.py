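"""NRF2-activation signature derivation.

From a labeled training set (activated tumors vs normal tissue, spanning two
tumor types), the signature is built in four steps:

1. ``vst_transform`` — variance-stabilizing transform of the raw counts:
   median-of-ratios size factors, then log2(count / size_factor + 1).
2. ``differential_expression`` — a pluggable tumor-vs-normal filter; the
   built-in test is Welch's t on the transformed values with BH adjustment,
   keeping genes with q < alpha and an absolute group-mean difference of at
   least ``lfc_min`` log2 units.
3. ``tumor_type_bias_rank`` — genes ranked by |d_r|, the absolute difference
   in mean transformed expression between the two tumor types among the
   training *tumors*, ascending, so the least type-confounded genes lead.
4. ``sequential_signature_selection`` — starting from the top two ranked
   genes and adding one per iteration, Ward-cluster the training samples on
   the growing gene set, cut at two clusters, and score each set with the
   machine-learning score MLS = L_Inter / L_Intra (the separation between
   the normal and tumor groups over the mean within-cluster pairwise
   distance; see :func:`mls_score` for the exact readings). The selected
   signature is the gene set maximizing MLS (ties -> smallest set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from .hotspots import bh_adjust


@dataclass(frozen=True)
class MlsTrace:
    """Trace of the sequential selection: (k, mls) pairs, selected size and
    gene list. ``mls`` is ``inf`` when a gene set collapses every
    within-cluster distance to zero."""

    trace: pd.DataFrame  # columns: k, mls
    selected_k: int
    selected_genes: list[str]


def vst_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform of a genes-by-samples count matrix.

    Size factors are median-of-ratios: the reference profile is the per-gene
    geometric mean over samples, computed on genes nonzero in every sample,
    and each sample's factor is the median of its ratios to the reference.
    Transformed values are log2(count / size_factor + 1), so a sample whose
    counts are a constant multiple of another's transforms identically. If
    no gene is nonzero in all samples the transform falls back to
    total-count scaling (factors proportional to column sums, geometric
    mean 1) with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero gene")
    allpos = (mat > 0).all(axis=1)
    if allpos.any():
        logref = np.log(mat[allpos]).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(mat[allpos]) - logref, axis=0))
    else:
        warnings.warn(
            "no gene nonzero in all samples; falling back to total-count scaling",
            stacklevel=2,
        )
        tot = mat.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
    return pd.DataFrame(
        np.log2(mat / sf[None, :] + 1.0), index=counts.index, columns=counts.columns
    )


def differential_expression(
    transformed: pd.DataFrame,
    is_tumor: pd.Series,
    lfc_min: float = 2.5,
    alpha: float = 0.05,
    de_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tumor-vs-normal differential-expression filter.

    Built-in test: per-gene Welch two-sample t on the transformed values,
    BH across genes; keeps genes with q < ``alpha`` and |mean(tumor) -
    mean(normal)| >= ``lfc_min`` (log2 units). Returns a frame with columns
    ``gene``, ``lfc``, ``p_value``, ``q_value``, ``sign``.

    Adapter point: pass ``de_table`` (columns ``gene``, ``lfc``,
    ``q_value``) computed by an external DE engine to bypass the built-in
    test; the same thresholds are then applied to it.
    """
    if de_table is not None:
        keep = (de_table["q_value"] < alpha) & (de_table["lfc"].abs() >= lfc_min)
        out = de_table.loc[keep].copy()
        out["sign"] = np.sign(out["lfc"]).astype(int)
        return out.reset_index(drop=True)

    labels = is_tumor.reindex(transformed.columns).to_numpy(dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    tum = transformed.loc[:, labels].to_numpy()
    norm = transformed.loc[:, ~labels].to_numpy()
    lfc = tum.mean(axis=1) - norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(tum, norm, axis=1, equal_var=False)
    # degenerate genes: zero variance in both groups
    p = np.where(np.isnan(p), np.where(lfc == 0, 1.0, 0.0), p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    q = bh_adjust(p)
    res = pd.DataFrame({
        "gene": transformed.index,
        "lfc": lfc,
        "p_value": p,
        "q_value": q,
        "sign": np.sign(lfc).astype(int),
    })
    keep = (res["q_value"] < alpha) & (res["lfc"].abs() >= lfc_min)
    return res.loc[keep].reset_index(drop=True)


def tumor_type_bias_rank(
    transformed: pd.DataFrame,
    genes: list[str],
    tumor_type: pd.Series,
) -> pd.DataFrame:
    """Rank DE genes by tumor-type bias |d_r|, ascending.

    d_r is the difference of mean transformed expression between the two
    tumor types over the training *tumor* samples given in ``tumor_type``
    (index = sample id, value = type code). Stable ascending sort on |d_r|,
    ties broken by gene name; rank 1 = least type-biased.
    """
    types = sorted(tumor_type.unique())
    if len(types) != 2:
        raise ValueError(f"need exactly 2 tumor types among training tumors, got {types}")
    g1 = tumor_type.index[tumor_type == types[0]]
    g2 = tumor_type.index[tumor_type == types[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("a tumor type has zero training tumors")
    sub = transformed.loc[genes]
    d_r = sub[g1].mean(axis=1) - sub[g2].mean(axis=1)
    out = pd.DataFrame({"gene": genes, "d_r": d_r.to_numpy()})
    out["abs_d_r"] = out["d_r"].abs()
    out = out.sort_values(["abs_d_r", "gene"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def mls_score(
    points: np.ndarray,
    is_tumor: np.ndarray,
    clusters: np.ndarray,
    inter: str = "min",
) -> float:
    """Machine-learning score MLS = L_Inter / L_Intra.

    L_Inter is the separation between the known normal and tumor groups:
    with ``inter="min"`` (default) the minimum Euclidean distance over
    normal-tumor sample pairs — the margin between the groups — and with
    ``inter="centroid"`` the distance between the two group centroids. The
    margin is the default because it is the quantity the sequential
    selection needs to optimize: it rises only while added genes separate
    tumors that previous genes left among the normals, giving the score
    trace an interior maximum at a complementary informative gene set,
    whereas a centroid/spread ratio is scale-invariant in gene-set size.

    L_Intra is the mean over clusters of the mean pairwise Euclidean
    distance within each cluster; singleton clusters contribute no pairs
    and are excluded from the average. A gene set separating samples so
    well that every cluster is internally identical (L_Intra = 0) scores
    ``inf``.
    """
    points = np.asarray(points, dtype=float)
    is_tumor = np.asarray(is_tumor, dtype=bool)
    if is_tumor.all() or (~is_tumor).all():
        raise ValueError("both label groups must be non-empty")
    if inter == "min":
        l_inter = float(cdist(points[~is_tumor], points[is_tumor]).min())
    elif inter == "centroid":
        l_inter = float(np.linalg.norm(
            points[is_tumor].mean(axis=0) - points[~is_tumor].mean(axis=0)
        ))
    else:
        raise ValueError(f"unknown inter mode {inter!r}")
    intra = []
    for c in np.unique(clusters):
        members = points[clusters == c]
        if len(members) >= 2:
            intra.append(float(pdist(members).mean()))
    l_intra = float(np.mean(intra)) if intra else 0.0
    if l_intra == 0.0:
        return float("inf")
    return l_inter / l_intra


def sequential_signature_selection(
    transformed: pd.DataFrame,
    ranked: pd.DataFrame,
    is_tumor: pd.Series,
    k_max: int | None = None,
) -> MlsTrace:
    """Grow the signature one ranked gene at a time, scoring each prefix.

    For k = 2..k_max, the top-k ranked genes define the feature space;
    training samples are Ward-clustered on Euclidean distances and cut into
    two clusters; MLS is recorded. The selected signature is the prefix with
    maximal MLS, smallest k on ties. Deterministic given its inputs.
    """
    genes = list(ranked.sort_values("rank")["gene"])
    if len(genes) < 2:
        raise ValueError("ranked list must contain >= 2 genes")
    if k_max is None:
        k_max = min(200, len(genes))
    if k_max > len(genes):
        warnings.warn(
            f"k_max={k_max} exceeds ranked list length {len(genes)}; truncating",
            stacklevel=2,
        )
        k_max = len(genes)
    labels = is_tumor.reindex(transformed.columns).to_numpy(dtype=bool)
    rows = []
    for k in range(2, k_max + 1):
        pts = transformed.loc[genes[:k]].to_numpy().T  # samples x genes
        clusters = fcluster(linkage(pts, method="ward"), t=2, criterion="maxclust")
        rows.append((k, mls_score(pts, labels, clusters)))
    trace = pd.DataFrame(rows, columns=["k", "mls"])
    best = int(trace.loc[trace["mls"].idxmax(), "k"])  # idxmax -> first (smallest k) on ties
    return MlsTrace(trace=trace, selected_k=best, selected_genes=genes[:best])
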