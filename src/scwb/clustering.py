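"""Subpopulation discovery from multiplexed marker matrices.

Marker abundances are z-scored per protein, then clustered two ways:
agglomerative hierarchical clustering (Euclidean distance, Ward-D2
criterion) and normalized spectral analysis of an epsilon-neighborhood
graph, where the ascending eigenvalues of the symmetric normalized
Laplacian suggest the number of clusters via the largest eigengap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.linalg import eigvalsh

from .phenotype import compare_groups

__all__ = [
    "ClusterResult",
    "EigenSpectrum",
    "scale_markers",
    "hcluster",
    "spectral_spectrum",
    "default_epsilon",
    "save_cluster_plots",
    "cluster_composition",
    "per_cluster_stats",
]


@dataclass
class ClusterResult:
    method: str
    k: int
    labels: np.ndarray  # 1..k, one per cell
    linkage_matrix: np.ndarray | None = None
    leaf_order: np.ndarray | None = None


@dataclass
class EigenSpectrum:
    epsilon: float
    eigenvalues: np.ndarray  # ascending
    suggested_k: int
    n_components: int
    disconnected: bool = False


def scale_markers(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-marker standardization: subtract mean, divide by sample SD (n-1)."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 cells to scale")
    sd = matrix.std(ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise ValueError(f"constant marker column(s): {', '.join(map(str, const))}")
    return (matrix - matrix.mean()) / sd


def hcluster(matrix: pd.DataFrame | np.ndarray, k: int) -> ClusterResult:
    """Ward-D2 hierarchical clustering on Euclidean distances, cut at k."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    Z = linkage(X, method="ward")  # Ward on raw observations == R ward.D2
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(method="hierarchical", k=int(labels.max()),
                         labels=labels, linkage_matrix=Z,
                         leaf_order=leaves_list(Z))


def default_epsilon(matrix, scale: float = 0.3) -> float:
    """Neighborhood radius: ``scale`` times the median pairwise distance."""
    d = pdist(np.asarray(matrix, dtype=float))
    return scale * float(np.median(d))


def spectral_spectrum(matrix: pd.DataFrame | np.ndarray,
                      epsilon: float | None = None) -> EigenSpectrum:
    """Eigenvalue spectrum of the normalized Laplacian of the eps-graph.

    Adjacency w_ij = 1 iff the Euclidean distance between cells i and j
    is <= epsilon (no self edges).  L = I - D^{-1/2} W D^{-1/2}; isolated
    cells keep degree 1 (self-loop convention) so every cell stays in
    the spectrum.  suggested_k is the argmax of successive gaps among
    the first min(10, n) ascending eigenvalues; the multiplicity of
    (near-)zero eigenvalues counts connected components.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if epsilon is None:
        epsilon = default_epsilon(X)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    D = squareform(pdist(X))
    W = (D <= epsilon).astype(float)
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    isolated = deg == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated cell(s) kept with "
                      "unit degree", stacklevel=2)
        deg = np.where(isolated, 1.0, deg)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - (d_inv_sqrt[:, None] * W) * d_inv_sqrt[None, :]
    evals = np.sort(eigvalsh(L))
    n_comp = int(np.sum(evals < 1e-8)) + int(isolated.sum())
    fully_disconnected = bool(np.all(W == 0))
    m = min(10, n)
    gaps = np.diff(evals[:m])
    suggested = int(np.argmax(gaps)) + 1 if gaps.size else 1
    if fully_disconnected:
        warnings.warn("epsilon graph has no edges", stacklevel=2)
        suggested = n_comp
    return EigenSpectrum(epsilon=float(epsilon), eigenvalues=evals,
                         suggested_k=suggested, n_components=n_comp,
                         disconnected=fully_disconnected)


def save_cluster_plots(result: ClusterResult, spectrum: EigenSpectrum,
                       out_dir) -> list:
    """Write the dendrogram and eigenvalue-scatter figures (PNG).

    The figures are the visual counterpart of the automated eigengap
    suggestion: the dendrogram for choosing k by eye, the ascending
    eigenvalue plot for reading off the gap.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    if result.linkage_matrix is not None:
        fig, ax = plt.subplots(figsize=(8, 4))
        dendrogram(result.linkage_matrix, ax=ax, no_labels=True,
                   color_threshold=0.0)
        ax.set_ylabel("Ward linkage height")
        p = out / "dendrogram.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    fig, ax = plt.subplots(figsize=(5, 4))
    m = min(10, spectrum.eigenvalues.size)
    ax.plot(np.arange(1, m + 1), spectrum.eigenvalues[:m], "o-")
    ax.axvline(spectrum.suggested_k + 0.5, ls="--", c="gray")
    ax.set_xlabel("eigenvalue index")
    ax.set_ylabel("Laplacian eigenvalue")
    ax.set_title(f"suggested k = {spectrum.suggested_k}")
    p = out / "eigenvalues.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def cluster_composition(labels, origins) -> pd.DataFrame:
    """Per-cluster fraction of member cells from each sample of origin."""
    labels = np.asarray(labels)
    origins = np.asarray(origins)
    if labels.shape != origins.shape:
        raise ValueError("labels and origins must have equal length")
    tab = pd.crosstab(pd.Series(labels, name="cluster"),
                      pd.Series(origins, name="origin"))
    return tab.div(tab.sum(axis=1), axis=0)


def per_cluster_stats(labels, records: pd.DataFrame,
                      terbb2_col: str = "is_terbb2_pos",
                      terbb2_auc_col: str = "auc_terbb2",
                      prs6_col: str = "auc_p-rs6",
                      min_group: int = 3) -> pd.DataFrame:
    """Within-cluster association of truncated-HER2 load with p-rs6.

    Per cluster: Spearman rho between truncated-HER2 and p-rs6 abundance
    among truncated-positive cells, and a two-tailed Mann-Whitney test of
    p-rs6 between truncated-positive and -negative cells.  Raw p-values
    are Benjamini-Hochberg adjusted across clusters.
    """
    from statsmodels.stats.multitest import multipletests

    labels = np.asarray(labels)
    if len(labels) != len(records):
        raise ValueError("labels and records must align")
    rows = []
    for cl in np.unique(labels):
        sub = records.iloc[np.flatnonzero(labels == cl)]
        pos = sub[sub[terbb2_col].astype(bool)]
        neg = sub[~sub[terbb2_col].astype(bool)]
        row: dict = {"cluster": cl, "n": len(sub), "n_pos": len(pos),
                     "n_neg": len(neg), "rho": np.nan, "rho_p": np.nan,
                     "mw_p": np.nan}
        if len(pos) >= min_group:
            sp = compare_groups(pos[terbb2_auc_col], pos[prs6_col], "spearman")
            row["rho"], row["rho_p"] = sp.statistic, sp.p_value
        if len(pos) >= min_group and len(neg) >= min_group:
            mw = compare_groups(pos[prs6_col].dropna(), neg[prs6_col].dropna(),
                                "mann-whitney")
            row["mw_p"] = mw.p_value
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in ("rho_p", "mw_p"):
        mask = out[col].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, col],
                                                 method="fdr_bh")[1]
        out[col + "_bh"] = adj
    return out
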