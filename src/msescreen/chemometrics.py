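"""Multivariate summaries of the presence/absence matrix.

All operations take the binary extracts x compounds occurrence matrix (a
pandas DataFrame with extract labels as index).  Occurrence, not
intensity, is the data: the screening output is qualitative, so the
chemometrics are presence/absence chemometrics.

* PCA on the column-centered binary matrix (no unit-variance scaling by
  default — scaling a binary matrix explodes the influence of rare
  compounds).
* Ward hierarchical clustering on Euclidean distances, using the
  squared-distance-updating (Ward.D2-style) criterion.
* Pearson correlation between extracts over their compound vectors, with
  R^2 alongside r.
* Venn partitioning: each compound assigned to the region of extracts
  that exactly contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA

__all__ = [
    "DegenerateInputError",
    "PCAResult",
    "run_pca",
    "WardTree",
    "ward_cluster",
    "correlate",
    "venn_partition",
    "region_sizes",
]


class DegenerateInputError(ValueError):
    """The matrix carries too little variation for the requested analysis."""


@dataclass
class PCAResult:
    scores: pd.DataFrame  # extracts x components
    loadings: pd.DataFrame  # compounds x components
    explained_fraction: np.ndarray  # per-component variance fraction

    def outlier(self) -> str:
        """Extract farthest (in score space) from the centroid of the rest."""
        dists = {}
        for label in self.scores.index:
            rest = self.scores.drop(index=label).mean(axis=0)
            dists[label] = float(np.linalg.norm(self.scores.loc[label] - rest))
        return max(dists, key=dists.get)


def _informative(matrix: pd.DataFrame) -> pd.DataFrame:
    keep = matrix.columns[matrix.nunique(axis=0) > 1]
    return matrix[keep]


def run_pca(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA of the binary occurrence matrix.

    Constant (all-present or all-absent) columns are removed before the
    decomposition; fewer than two informative columns is a degenerate
    input.  The number of retained components is min(extracts - 1,
    compounds), i.e. the full rank of the centered matrix, so the
    explained fractions sum to 1.
    """
    if len(matrix) < 2:
        raise DegenerateInputError("need at least 2 extracts")
    informative = _informative(matrix)
    if informative.shape[1] < 1:
        raise DegenerateInputError("no informative (non-constant) columns")
    X = informative.to_numpy(dtype=float)
    if scale:
        X = X / X.std(axis=0, ddof=0)
    n_comp = min(len(matrix) - 1, informative.shape[1])
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    if center:
        pca = PCA(n_components=n_comp)
        scores = pca.fit_transform(X)
        loadings = pca.components_.T
        explained = pca.explained_variance_ratio_
    else:
        # uncentered decomposition via plain SVD
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        scores = (u * s)[:, :n_comp]
        loadings = vt[:n_comp].T
        explained = (s[:n_comp] ** 2) / (s**2).sum()
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=informative.columns, columns=comp_names),
        explained_fraction=explained,
    )


@dataclass
class WardTree:
    """A Ward merge tree over extracts (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: List[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def outgroup(self) -> Optional[str]:
        """The extract joining the tree last as a singleton, if any."""
        n = len(self.labels)
        for row in self.linkage[::-1]:
            a, b = int(row[0]), int(row[1])
            leaves = [i for i in (a, b) if i < n]
            if leaves:
                return self.labels[leaves[0]]
        return None


def ward_cluster(matrix: pd.DataFrame) -> WardTree:
    """Ward hierarchical clustering of extracts on Euclidean distance.

    Uses the variance-minimizing criterion with squared-distance updating
    on raw Euclidean distances.  Deterministic; distance ties resolve to
    the earlier (lexicographically ordered input) pair.
    """
    if len(matrix) < 2:
        raise DegenerateInputError("need at least 2 extracts to cluster")
    ordered = matrix.sort_index()
    Z = linkage(ordered.to_numpy(dtype=float), method="ward")
    return WardTree(linkage=Z, labels=list(ordered.index))


def correlate(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between extracts (rows).

    Zero-variance extracts yield missing values for their pairs.  The
    squared values (R^2) are ``correlate(m) ** 2``.
    """
    r = matrix.T.astype(float).corr()
    np.fill_diagonal(r.values, 1.0)
    variances = matrix.var(axis=1)
    for label in matrix.index[variances == 0]:
        r.loc[label, :] = np.nan
        r.loc[:, label] = np.nan
    return r


def venn_partition(matrix: pd.DataFrame) -> Dict[Tuple[str, ...], List[str]]:
    """Partition compounds by the exact subset of extracts containing them.

    Keys are sorted tuples of extract labels; regions are disjoint and
    cover every compound with at least one presence.  Compounds absent
    everywhere (possible in hand-built matrices) land under the empty
    tuple so the partition property still holds.
    """
    regions: Dict[Tuple[str, ...], List[str]] = {}
    for compound in matrix.columns:
        present = tuple(sorted(matrix.index[matrix[compound] == 1]))
        regions.setdefault(present, []).append(compound)
    return regions


def region_sizes(
    regions: Dict[Tuple[str, ...], List[str]]
) -> Dict[Tuple[str, ...], int]:
    return {k: len(v) for k, v in regions.items()}
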