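"""Hierarchical clustering of dysregulated transcripts across genotype tracks.

Transcripts overexpressed on *Dusp1* deletion fall into groups by how much
of the effect survives in the *Zfp36aa* background: TTP-independent
clusters, a fully TTP-dependent cluster, and partially dependent ones.
Agglomerative clustering with average linkage on Pearson-correlation
distance between row-standardized expression profiles — the conventional
choice for expression heat maps — separates those patterns; the tree is
cut to exactly k clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = ["ClusterResult", "cluster_genes", "summarize_clusters", "relative_tracks"]


@dataclass(frozen=True)
class ClusterResult:
    labels: pd.Series  # probe -> 1..k
    linkage_matrix: np.ndarray  # scipy merge list (rows: left, right, height, size)
    k: int
    metric: str
    method: str

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def relative_tracks(
    log2_matrix: pd.DataFrame, design: pd.DataFrame, reference: tuple[str, str] = ("WT", "LPS")
) -> pd.DataFrame:
    """Per-genotype/treatment mean log2 expression relative to a reference.

    Mirrors heat-map construction: each track is a (genotype, treatment)
    group mean, centred on the LPS-treated wild-type mean.
    """
    tracks = {}
    for (g, t), sub in design.groupby(["genotype", "treatment"], sort=True):
        tracks[f"{g}_{t}"] = log2_matrix[sub["sample_id"].tolist()].mean(axis=1)
    out = pd.DataFrame(tracks)
    ref = f"{reference[0]}_{reference[1]}"
    if ref not in out.columns:
        raise ValueError(f"reference track {ref!r} absent from design")
    return out.sub(out[ref], axis=0)


def cluster_genes(
    profiles: pd.DataFrame,
    k: int,
    method: str = "average",
    metric: str = "pearson",
) -> ClusterResult:
    """Cluster row profiles (probes x tracks) into exactly k groups.

    Rows are standardized (mean 0, SD 1) and clustered on 1 - Pearson
    correlation. Constant rows, whose correlation is undefined, are held
    out with a warning and assigned afterwards to the cluster with the
    nearest centroid in Euclidean distance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} probes, got {len(profiles)}")
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 tracks")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    constant = sd == 0.0
    if constant.all():
        # All profiles identical in shape: a single degenerate tree.
        labels = pd.Series(1, index=profiles.index, name="cluster")
        if k > 1:
            raise ValueError("all rows constant: cannot form k > 1 clusters")
        return ClusterResult(labels, np.empty((0, 4)), k, metric, method)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s): assigned by Euclidean fallback"
        )

    if metric == "pearson":
        Z = (X[~constant] - X[~constant].mean(axis=1, keepdims=True)) / sd[
            ~constant, None
        ]
        dist = pdist(Z, metric="correlation")
    elif metric == "euclidean":
        Z = X[~constant]
        dist = pdist(Z, metric="euclidean")
    else:
        raise ValueError("metric must be 'pearson' or 'euclidean'")
    merge = linkage(dist, method=method)
    core_labels = fcluster(merge, t=k, criterion="maxclust")

    labels = np.empty(len(profiles), dtype=int)
    labels[~constant] = core_labels
    if constant.any():
        centroids = np.stack(
            [X[~constant][core_labels == c].mean(axis=0) for c in range(1, k + 1)]
        )
        for i in np.where(constant)[0]:
            labels[i] = 1 + int(np.argmin(((centroids - X[i]) ** 2).sum(axis=1)))
    series = pd.Series(labels, index=profiles.index, name="cluster")
    return ClusterResult(series, merge, k, metric, method)


def summarize_clusters(result: ClusterResult, expression: pd.DataFrame) -> pd.DataFrame:
    """Box-and-whisker statistics per cluster and track.

    Quartiles use the linear-interpolation quantile rule; whiskers are the
    most extreme values within 1.5 x IQR of the quartiles.
    """
    rows = []
    for c in range(1, result.k + 1):
        members = result.labels.index[result.labels == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        sub = expression.loc[members]
        for track in expression.columns:
            v = sub[track].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            in_lo = v[v >= q1 - 1.5 * iqr]
            in_hi = v[v <= q3 + 1.5 * iqr]
            rows.append(
                {
                    "cluster": c,
                    "track": track,
                    "n": len(v),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": in_lo.min(),
                    "whisker_high": in_hi.max(),
                }
            )
    return pd.DataFrame(rows)
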