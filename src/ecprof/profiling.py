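"""Area-level aggregation and multivariate profiling.

Each stitched area contributes one row of the 47 registry features.
Rows are z-scored per feature, then summarised two ways: PCA (SVD of the
centered matrix, deterministic sign convention) and average-linkage
hierarchical clustering on Euclidean row distances with leaves reordered
by average feature value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .junctions import JunctionSet
from .morphometry import FeatureDescriptor, feature_registry
from .notch import ClusterSummary, NotchResult

__all__ = ["ANNOTATION_COLUMNS", "ProfileResult", "aggregate_area",
           "normalize_features", "pca_profile", "hcluster", "profile_table"]

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["area_id", "cell_model", "treatment", "replicate",
                      "area"]


@dataclass
class ProfileResult:
    """PCA + hierarchical-clustering summary of a feature table."""

    scores: np.ndarray | None = None            # rows × components
    loadings: np.ndarray | None = None          # features × components
    explained_variance_ratio: np.ndarray | None = None
    linkage: np.ndarray | None = None           # scipy linkage matrix
    leaf_order: list[int] | None = None
    feature_names: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        out = {"feature_names": self.feature_names}
        for k in ("scores", "loadings", "explained_variance_ratio",
                  "linkage"):
            v = getattr(self, k)
            out[k] = None if v is None else np.asarray(v).tolist()
        out["leaf_order"] = self.leaf_order
        return out


def aggregate_area(cell_table: pd.DataFrame,
                   registry: list[FeatureDescriptor] | None = None,
                   jset: JunctionSet | None = None,
                   notch: NotchResult | None = None,
                   clusters: ClusterSummary | None = None,
                   annotations: dict | None = None) -> dict:
    """Collapse one area's cell table into a single feature row.

    Per-cell features aggregate by mean; area-level statistics (J_n, NOTCH
    percentages, cluster features, cell count) come from their definitions.
    """
    if cell_table.empty:
        raise ValueError("no cells in area")
    registry = registry or feature_registry()
    n_cells = len(cell_table)

    stats: dict[str, float] = {"cell_count": float(n_cells)}
    stats["jn"] = float(cell_table["jn_count"].mean())
    cats = cell_table["notch_category"]
    for key, cat in (("pct_nneg", "Nneg"), ("pct_ncyt", "Ncyt"),
                     ("pct_nnuc", "Nnuc")):
        stats[key] = 100.0 * float((cats == cat).sum()) / n_cells
    if notch is not None:
        # prefer the classifier's own fractions when available (identical
        # by construction when the table covers all retained cells)
        for key, cat in (("pct_nneg", "Nneg"), ("pct_ncyt", "Ncyt"),
                         ("pct_nnuc", "Nnuc")):
            stats[key] = notch.fractions[cat]
    if clusters is None:
        sizes = (cell_table.loc[cats == "Nnuc", "cluster_id"]
                 .value_counts().to_numpy())
        total = sizes.sum()
        stats["notch_n_clusters"] = float(len(sizes))
        stats["notch_mean_cluster_size"] = float(sizes.mean()) if len(sizes) \
            else 0.0
        stats["notch_max_cluster_size"] = float(sizes.max()) if len(sizes) \
            else 0.0
        stats["notch_frac_in_multi"] = (
            float(sizes[sizes >= 2].sum()) / total if total else 0.0)
    else:
        stats["notch_n_clusters"] = float(clusters.n_clusters)
        stats["notch_mean_cluster_size"] = clusters.mean_size
        stats["notch_max_cluster_size"] = float(clusters.max_size)
        stats["notch_frac_in_multi"] = clusters.frac_in_multi

    row: dict[str, object] = dict(annotations or {})
    for d in registry:
        if d.aggregation == "cell_mean":
            row[d.name] = float(cell_table[d.source].mean())
        else:
            row[d.name] = stats[d.source]
    return row


def profile_table(rows: list[dict],
                  registry: list[FeatureDescriptor] | None = None
                  ) -> pd.DataFrame:
    """Stack per-area rows into a FeatureTable (annotations first)."""
    registry = registry or feature_registry()
    names = [d.name for d in registry]
    df = pd.DataFrame(rows)
    anns = [c for c in ANNOTATION_COLUMNS if c in df.columns]
    return df[anns + names]


def normalize_features(table: pd.DataFrame,
                       feature_names: list[str] | None = None
                       ) -> pd.DataFrame:
    """Per-feature z-score across rows (ddof=1); constant features → 0."""
    if len(table) < 2:
        raise ValueError("normalization requires >= 2 rows")
    feature_names = feature_names or [
        c for c in table.columns if c not in ANNOTATION_COLUMNS]
    out = table.copy()
    for c in feature_names:
        v = table[c].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd <= 0 or not np.isfinite(sd):
            log.info("feature %s has zero variance; set to 0", c)
            out[c] = 0.0
        else:
            out[c] = (v - v.mean()) / sd
    return out


def _matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = [c for c in table.columns if c not in ANNOTATION_COLUMNS]
    return table[names].to_numpy(dtype=float), names


def pca_profile(table: pd.DataFrame, k: int = 3,
                result: ProfileResult | None = None) -> ProfileResult:
    """PCA of the standardized feature table via SVD.

    ``explained_variance_ratio_j = s_j²/Σs²`` over all components; the
    returned scores/loadings keep the first ``k``.  Sign convention: the
    largest-magnitude loading of each component is made positive.
    """
    X, names = _matrix(table)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires >= 2 rows")
    if not 1 <= k <= min(n - 1, X.shape[1]):
        raise ValueError(f"k={k} out of range for table {X.shape}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = s ** 2 / (s ** 2).sum() if (s ** 2).sum() > 0 else s * 0
    # deterministic signs
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    res = result or ProfileResult()
    res.scores = (U * s)[:, :k]
    res.loadings = Vt[:k].T
    res.explained_variance_ratio = evr
    res.feature_names = names
    return res


def _reorder_leaves(Z: np.ndarray, leaf_value: np.ndarray) -> list[int]:
    """Leaf order with subtrees at each merge ordered by average value."""
    n = Z.shape[0] + 1
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    avg: dict[int, float] = {i: float(leaf_value[i]) for i in range(n)}
    for m, (a, b, _h, _c) in enumerate(Z):
        a, b = int(a), int(b)
        first, second = (a, b) if avg[a] <= avg[b] else (b, a)
        mem = members.pop(first) + members.pop(second)
        members[n + m] = mem
        avg[n + m] = float(np.mean([leaf_value[i] for i in mem]))
    return members[2 * n - 2]


def hcluster(table: pd.DataFrame, result: ProfileResult | None = None,
             method: str = "average") -> ProfileResult:
    """Average-linkage (UPGMA) clustering of rows on Euclidean distance.

    Leaf order follows the "ordered by average value" convention: at every
    merge the subtree with the lower average feature value comes first.
    """
    X, names = _matrix(table)
    if X.shape[0] < 2:
        raise ValueError("clustering requires >= 2 rows")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=method)
    res = result or ProfileResult()
    res.linkage = Z
    res.leaf_order = _reorder_leaves(Z, X.mean(axis=1))
    res.feature_names = names
    return res
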