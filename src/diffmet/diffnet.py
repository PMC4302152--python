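"""Differential co-expression networks: D, S and module detection.

The metabolite network under one condition is its signed Pearson
correlation matrix A (the adjacency). Comparing two conditions, the
soft-thresholded difference matrix

    D_ij = |(r_ij,1 - r_ij,2) / 2| ** (beta / 2)

emphasises pairs whose correlation changes (beta, a positive integer,
default 5, de-emphasises small differences), and the similarity matrix

    S_ij = (1 - D_ij) * |r_ij,1| * |r_ij,2|

is high where correlations are both strong and equal across conditions
(when the conditions agree exactly, S_ij = r_ij ** 2). Differential
("plastic") modules are found by average-linkage hierarchical clustering
with D as the adjacency, i.e. on the dissimilarity 1 - D (optionally
1 - TOM(D)); preserved modules by clustering on 1 - S.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import (
    UNASSIGNED,
    CorrelationMatrix,
    DifferenceMatrix,
    FeatureTable,
    ModuleAssignment,
    SimilarityMatrix,
)

#: module labels in assignment order (largest module first), WGCNA style
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


class DataError(ValueError):
    pass


def correlation_matrix(
    table: FeatureTable,
    selector,
    condition: Optional[str] = None,
) -> CorrelationMatrix:
    """Signed Pearson correlations across one condition's samples.

    ``selector`` picks the condition's samples: a dict of annotation
    equalities (e.g. ``{"dev_temp": 18}``), a callable on the sample
    annotation frame returning a boolean mask, or a boolean mask/array
    of sample ids.
    """
    if isinstance(selector, dict):
        mask = np.ones(table.n_samples, dtype=bool)
        for key, val in selector.items():
            mask &= (table.samples[key] == val).to_numpy()
        label = ",".join(f"{k}={v}" for k, v in selector.items())
    elif callable(selector):
        mask = np.asarray(selector(table.samples), dtype=bool)
        label = getattr(selector, "__name__", "condition")
    else:
        arr = np.asarray(selector)
        if arr.dtype == bool:
            mask = arr
        else:
            mask = table.samples.index.isin(arr)
        label = "condition"
    sub = table.subset_samples(mask)
    if sub.n_samples < 4:
        raise DataError(
            f"condition {condition or label!r} has {sub.n_samples} samples; need >= 4"
        )
    X = sub.intensities.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DataError("intensities contain missing values; run QC/imputation first")
    sd = X.std(axis=1)
    if (sd == 0).any():
        fid = sub.feature_ids[int(np.argmax(sd == 0))]
        raise DataError(f"feature {fid!r} has zero variance in this condition")
    R = np.clip(np.corrcoef(X), -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R, sub.feature_ids, condition or label, sub.n_samples)


def _check_pair(C1: CorrelationMatrix, C2: CorrelationMatrix) -> None:
    if C1.values.shape != C2.values.shape or C1.features != C2.features:
        raise ValueError("correlation matrices must share features and order")


def difference_matrix(
    C1: CorrelationMatrix, C2: CorrelationMatrix, beta: int = 5
) -> DifferenceMatrix:
    """``D = |(A - A') / 2| ** (beta / 2)`` with a zero diagonal."""
    _check_pair(C1, C2)
    if not (isinstance(beta, (int, np.integer)) and beta >= 1):
        raise ValueError("beta must be a positive integer")
    D = np.abs((C1.values - C2.values) / 2.0) ** (beta / 2.0)
    np.fill_diagonal(D, 0.0)
    return DifferenceMatrix(D, list(C1.features), int(beta))


def similarity_matrix(
    C1: CorrelationMatrix, C2: CorrelationMatrix, beta: int = 5
) -> SimilarityMatrix:
    """``S = (1 - D) * |A| * |A'|``; unit diagonal, entries in [0, 1]."""
    _check_pair(C1, C2)
    D = difference_matrix(C1, C2, beta).values
    S = (1.0 - D) * np.abs(C1.values) * np.abs(C2.values)
    return SimilarityMatrix(S, list(C1.features), int(beta))


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap of a nonnegative adjacency (unsigned TOM)."""
    A = np.asarray(adjacency, dtype=float)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A) / (kmin + 1.0 - A)
    T = np.nan_to_num(T, nan=0.0)
    np.fill_diagonal(T, 1.0)
    return T


def detect_modules(
    dissimilarity: np.ndarray,
    feature_ids: Sequence[str],
    min_size: int = 10,
    cut_fraction: float = 0.95,
    kind: str = "differential",
) -> ModuleAssignment:
    """Average-linkage clustering of a dissimilarity into modules.

    The dendrogram is cut at ``cut_fraction`` times the maximum merge
    height; resulting clusters smaller than ``min_size`` are left
    unassigned ("grey"). Modules are named by decreasing size with a
    fixed colour palette, ties broken by first member position, so the
    labelling is deterministic and invariant (up to renaming) to feature
    order.
    """
    W = np.asarray(dissimilarity, dtype=float)
    ids = list(feature_ids)
    n = W.shape[0]
    if W.shape != (n, n) or n != len(ids):
        raise ValueError("dissimilarity must be square and match feature ids")
    if np.any(W < 0):
        raise ValueError("dissimilarity must be nonnegative")
    params = {"min_size": min_size, "cut_fraction": cut_fraction}

    if n < min_size:
        warnings.warn(
            f"{n} features is fewer than min_size={min_size}; all features unassigned",
            stacklevel=2,
        )
        return ModuleAssignment(pd.Series(UNASSIGNED, index=ids), kind, params)

    sym = np.maximum(W, W.T)
    np.fill_diagonal(sym, 0.0)
    Z = linkage(squareform(sym, checks=False), method="average")
    height = cut_fraction * float(Z[:, 2].max())
    raw = fcluster(Z, t=height, criterion="distance")

    # order clusters by size (desc), then by first member, for stable names
    order = sorted(
        np.unique(raw),
        key=lambda c: (-int((raw == c).sum()), int(np.argmax(raw == c))),
    )
    labels = pd.Series(UNASSIGNED, index=ids, dtype=object)
    assigned = 0
    for c in order:
        members = raw == c
        if members.sum() < min_size:
            continue
        name = (
            MODULE_COLORS[assigned]
            if assigned < len(MODULE_COLORS)
            else f"module{assigned + 1}"
        )
        labels.iloc[np.flatnonzero(members)] = name
        assigned += 1
    if assigned == 1 and int((labels != UNASSIGNED).sum()) == n:
        warnings.warn(
            "all features fell into a single module; dissimilarity may be degenerate",
            stacklevel=2,
        )
    return ModuleAssignment(labels, kind, params)


def differential_modules(
    C1: CorrelationMatrix,
    C2: CorrelationMatrix,
    beta: int = 5,
    min_size: int = 10,
    cut_fraction: float = 0.95,
    tom: bool = False,
) -> ModuleAssignment:
    """Modules whose correlation structure changes between conditions.

    D acts as the adjacency of the "change" network; clustering runs on
    the dissimilarity ``1 - D`` (or ``1 - TOM(D)`` with ``tom=True``).
    """
    D = difference_matrix(C1, C2, beta).values
    dissim = 1.0 - (tom_similarity(D) if tom else D)
    np.fill_diagonal(dissim, 0.0)
    out = detect_modules(dissim, C1.features, min_size, cut_fraction, kind="differential")
    out.params.update({"beta": int(beta), "tom": tom})
    return out


def preserved_modules(
    C1: CorrelationMatrix,
    C2: CorrelationMatrix,
    beta: int = 5,
    min_size: int = 10,
    cut_fraction: float = 0.95,
) -> ModuleAssignment:
    """Modules whose strong correlation structure is shared by both conditions."""
    S = similarity_matrix(C1, C2, beta).values
    dissim = 1.0 - S
    np.fill_diagonal(dissim, 0.0)
    out = detect_modules(dissim, C1.features, min_size, cut_fraction, kind="preserved")
    out.params["beta"] = int(beta)
    return out


def export_edges(C: CorrelationMatrix, threshold: float = 0.7) -> pd.DataFrame:
    """Undirected edge list of pairs with |r| >= threshold.

    Columns ``source, target, r, sign`` (sign "+"/"-"), one row per
    unordered pair, suitable for import into Cytoscape.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    R = C.values
    iu, ju = np.triu_indices(R.shape[0], k=1)
    keep = np.abs(R[iu, ju]) >= threshold
    rows = {
        "source": [C.features[i] for i in iu[keep]],
        "target": [C.features[j] for j in ju[keep]],
        "r": R[iu[keep], ju[keep]],
    }
    df = pd.DataFrame(rows)
    df["sign"] = np.where(df["r"] >= 0, "+", "-") if len(df) else pd.Series(dtype=object)
    return df


def jaccard(a: Sequence, b: Sequence) -> float:
    """Jaccard index between two feature sets (module-recovery metric)."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def best_match(assignment: ModuleAssignment, truth: Sequence) -> tuple[Optional[str], float]:
    """Detected module best matching a planted feature set, by Jaccard."""
    best, best_j = None, 0.0
    for label, members in assignment.modules().items():
        j = jaccard(members, truth)
        if j > best_j:
            best, best_j = label, j
    return best, best_j
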