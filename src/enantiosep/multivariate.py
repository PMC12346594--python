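"""Multivariate comparison of chromatographic systems.

Rows are chromatographic systems (CSP x mobile phase); columns are the
per-analyte features the screening and thermodynamic stages produce:
directed resolution (Rs signed by elution order), the Q value, and the
enantioselective Gibbs free energy difference ddG.  On this matrix the
module computes (i) a system-by-system Pearson correlation matrix over
pairwise-complete observations, with cells left missing when too few
complete pairs or no variance remain; (ii) hierarchical clustering on
standardized features with Euclidean distances; (iii) PCA of the
standardized features, with explained-variance fractions and per-variable
cos2 quality-of-representation; and (iv) a deterministic
representative-set selection that cuts the dendrogram at k clusters and
picks each cluster's medoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .dataio import Analyte, ScreeningTable, ValidationError
from .metrics import directed_resolution
from .thermo import EnantioThermo

__all__ = [
    "FeatureMatrix",
    "CorrelationMatrix",
    "ClusterResult",
    "PCAResult",
    "SelectionResult",
    "build_feature_matrix",
    "pairwise_correlation",
    "hierarchical_cluster",
    "pca",
    "select_representative_set",
]


@dataclass
class FeatureMatrix:
    """Systems x features table; cells may be missing (NaN), never imputed here."""

    data: pd.DataFrame  # index: system_id; columns carry units in `units`
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate system identifiers: {dupes}")


def build_feature_matrix(
    screening: ScreeningTable,
    thermo: Mapping[tuple[str, str, str], EnantioThermo] | None = None,
) -> FeatureMatrix:
    """Assemble the systems x (dirRs, Q, ddG per analyte) matrix.

    One row per (csp, eluent) system.  Coelution contributes directed
    Rs = 0 and leaves Q/ddG missing; missing cells stay missing.
    ``thermo`` maps (csp, eluent, analyte) to fitted enantioselective
    thermodynamics and may be omitted for an Rs-only matrix.
    """
    rows: dict[str, dict[str, float]] = {}
    units: dict[str, str] = {}
    for r in screening:
        sid = r.system.system_id
        row = rows.setdefault(sid, {})
        col = f"dirRs_{r.analyte.value}"
        if col in row:
            raise ValidationError(f"duplicate cell for {sid}/{r.analyte.value}")
        row[col] = directed_resolution(r.rs, r.eeo)
        units[col] = "dimensionless (signed)"
        if thermo is not None:
            key = (r.system.csp_id, r.system.eluent_label, r.analyte.value)
            th = thermo.get(key)
            qcol, gcol = f"Q_{r.analyte.value}", f"ddG_{r.analyte.value}"
            units[qcol] = "dimensionless"
            units[gcol] = "J/mol"
            if th is not None and th.Q is not None:
                row[qcol] = th.Q
                row[gcol] = th.ddG_at_Tref
            else:
                row.setdefault(qcol, np.nan)
                row.setdefault(gcol, np.nan)
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame = frame[sorted(frame.columns)]
    return FeatureMatrix(data=frame, units=units)


@dataclass
class CorrelationMatrix:
    """Pearson r between system rows over pairwise-complete features."""

    r: pd.DataFrame
    n_complete: pd.DataFrame  # complete observation count per cell
    mask: pd.DataFrame  # True where r is missing/incalculable


def pairwise_correlation(m: FeatureMatrix, min_pairs: int = 3) -> CorrelationMatrix:
    """Correlate every pair of system rows on their shared complete features.

    A cell becomes missing when fewer than ``min_pairs`` features are
    complete in both rows, or when either row has zero variance over the
    shared features (r undefined).
    """
    X = m.data
    if len(X) < 2:
        raise ValueError("need at least two systems")
    ids = X.index
    n = len(ids)
    rmat = np.full((n, n), np.nan)
    cmat = np.zeros((n, n), dtype=int)
    values = X.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i, n):
            both = ~np.isnan(values[i]) & ~np.isnan(values[j])
            cnt = int(both.sum())
            cmat[i, j] = cmat[j, i] = cnt
            if cnt < min_pairs:
                continue
            xi, xj = values[i, both], values[j, both]
            if np.std(xi) == 0.0 or np.std(xj) == 0.0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            rmat[i, j] = rmat[j, i] = r
    rdf = pd.DataFrame(rmat, index=ids, columns=ids)
    return CorrelationMatrix(
        r=rdf,
        n_complete=pd.DataFrame(cmat, index=ids, columns=ids),
        mask=rdf.isna(),
    )


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping zero-variance feature(s): {dropped}")
    Z = (X.loc[:, keep] - mu[keep]) / sd[keep]
    return Z


def _impute(X: pd.DataFrame, method: str = "mean", max_iter: int = 50) -> pd.DataFrame:
    """Fill missing cells: column-mean by default, iterative rank-1 PCA optionally."""
    if not X.isna().any().any():
        return X.copy()
    if method == "mean":
        return X.fillna(X.mean(axis=0))
    if method == "iterative_pca":
        filled = X.fillna(X.mean(axis=0))
        mask = X.isna().to_numpy()
        for _ in range(max_iter):
            mu = filled.mean(axis=0)
            centered = filled - mu
            u, s, vt = np.linalg.svd(centered.to_numpy(dtype=float), full_matrices=False)
            approx = np.outer(u[:, 0] * s[0], vt[0]) + mu.to_numpy()
            new = filled.to_numpy().copy()
            new[mask] = approx[mask]
            delta = np.nanmax(np.abs(new - filled.to_numpy()))
            filled = pd.DataFrame(new, index=X.index, columns=X.columns)
            if delta < 1e-10:
                break
        return filled
    raise ValueError(f"unknown imputation method {method!r}")


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    labels: pd.Series  # cluster id per system, cut at k
    k: int
    method: str
    distances: pd.DataFrame  # Euclidean distances on scaled (imputed) features
    scaled: pd.DataFrame


def hierarchical_cluster(
    m: FeatureMatrix,
    linkage: str = "complete",
    k: int = 5,
    impute: str = "mean",
) -> ClusterResult:
    """Agglomerative clustering of systems on standardized features.

    Features are imputed (mean by default), standardized to zero mean and
    unit variance, and clustered with Euclidean distances under the
    requested linkage; the dendrogram is cut at ``k`` clusters.
    """
    if k > len(m.data):
        raise ValueError(f"k = {k} exceeds the number of systems ({len(m.data)})")
    if linkage not in ("single", "complete", "average", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    Z = _standardize(_impute(m.data, impute))
    # row order independence: cluster on a canonical (sorted) row order
    Z = Z.sort_index()
    dist = pdist(Z.to_numpy(dtype=float), metric="euclidean")
    link = hierarchy.linkage(dist, method=linkage)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return ClusterResult(
        linkage_matrix=link,
        labels=pd.Series(labels, index=Z.index, name="cluster"),
        k=k,
        method=linkage,
        distances=pd.DataFrame(squareform(dist), index=Z.index, columns=Z.index),
        scaled=Z,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # systems x components
    loadings: pd.DataFrame  # variables x components (eigenvector basis)
    explained_variance_ratio: np.ndarray
    cos2: pd.DataFrame  # per-variable quality of representation

    @property
    def n_components(self) -> int:
        return len(self.explained_variance_ratio)


def pca(m: FeatureMatrix, impute: str = "mean", standardize: bool = True) -> PCAResult:
    """PCA of (by default standardized) features with per-variable cos2.

    Zero-variance features (after imputation) are dropped with a
    warning.  On standardized data the variable coordinates
    (eigenvector x sqrt(eigenvalue)) are variable-component
    correlations, so cos2 = coordinate^2.  ``standardize=False``
    decomposes the raw covariance instead, preserving the features'
    variance ratios.
    """
    Z = _impute(m.data, impute)
    if standardize:
        Z = _standardize(Z)
    else:
        sd = Z.std(axis=0, ddof=0)
        if (sd == 0).any():
            dropped = list(Z.columns[sd == 0])
            warnings.warn(f"dropping zero-variance feature(s): {dropped}")
            Z = Z.loc[:, sd > 0]
    Z = Z.sort_index()
    if len(Z) < 2:
        raise ValueError("need at least two systems for PCA")
    model = PCA()
    scores = model.fit_transform(Z.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(model.n_components_)]
    # correlation-scale coordinates; population eigenvalues to match the
    # population standardization above
    eigvals = model.explained_variance_ * (len(Z) - 1) / len(Z)
    coords = model.components_.T * np.sqrt(eigvals)
    return PCAResult(
        scores=pd.DataFrame(scores, index=Z.index, columns=comp_names),
        loadings=pd.DataFrame(
            model.components_.T, index=Z.columns, columns=comp_names
        ),
        explained_variance_ratio=model.explained_variance_ratio_,
        cos2=pd.DataFrame(coords**2, index=Z.columns, columns=comp_names),
    )


@dataclass
class SelectionResult:
    selected: list[str]
    by_cluster: dict[int, str]
    pca_coordinates: pd.DataFrame


def select_representative_set(
    cluster: ClusterResult, pca_result: PCAResult | None = None, k: int = 5
) -> SelectionResult:
    """Pick one representative system per cluster (the medoid).

    The dendrogram is cut at ``k`` clusters (recut when the stored cut
    differs) and within each cluster the system with minimum mean
    distance to its cluster-mates is selected; ties break
    lexicographically by system identifier.  Deterministic given inputs.
    """
    if k == cluster.k:
        labels = cluster.labels
    else:
        if k > len(cluster.labels):
            raise ValueError(f"k = {k} exceeds the number of systems")
        flat = hierarchy.fcluster(cluster.linkage_matrix, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=cluster.labels.index, name="cluster")
    by_cluster: dict[int, str] = {}
    for cid in sorted(labels.unique()):
        members = sorted(labels.index[labels == cid])
        if len(members) == 1:
            by_cluster[int(cid)] = members[0]
            continue
        sub = cluster.distances.loc[members, members]
        mean_d = sub.sum(axis=1) / (len(members) - 1)
        best = min(members, key=lambda s: (mean_d[s], s))
        by_cluster[int(cid)] = best
    selected = [by_cluster[c] for c in sorted(by_cluster)]
    coords = (
        pca_result.scores.loc[selected]
        if pca_result is not None
        else pd.DataFrame(index=selected)
    )
    return SelectionResult(selected=selected, by_cluster=by_cluster, pca_coordinates=coords)
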