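"""Cluster mutations with statistically indistinguishable CCF trajectories.

Two mutations belong to the same clone when their ploidy-corrected VAF
trajectories agree at every sequenced sample. The distance is therefore a
worst-sample z statistic, and clusters are grown by average-linkage
agglomeration that stops once the closest pair of clusters differs by at
least ``z_threshold`` pooled standard errors somewhere. The merge loop is
implemented here directly so the stopping rule and the smallest-id
tie-break are exact and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ccf import CcfMatrix
from .config import DEFAULT_CONFIG, PipelineConfig

_SE_FLOOR = 1e-12


class IncomparableError(ValueError):
    """Two mutations share no sample with finite estimates."""


@dataclass
class MutationCluster:
    cluster_id: str
    members: list[str]
    centroid: pd.Series = field(repr=False, default=None)
    centroid_se: pd.Series = field(repr=False, default=None)


def trajectory_distance(mut_i: str, mut_j: str, matrix: CcfMatrix) -> float:
    """Worst-sample z: max over shared samples of |ccf_i - ccf_j| / pooled se."""
    ci, cj = matrix.ccf.loc[mut_i], matrix.ccf.loc[mut_j]
    si, sj = matrix.se.loc[mut_i], matrix.se.loc[mut_j]
    shared = ci.notna() & cj.notna()
    if not shared.any():
        raise IncomparableError(f"{mut_i} and {mut_j} share no samples")
    diff = (ci - cj)[shared].abs().to_numpy()
    pooled = np.sqrt(si[shared] ** 2 + sj[shared] ** 2).to_numpy()
    return float(np.max(diff / np.maximum(pooled, _SE_FLOOR)))


def _pair_distance_matrix(matrix: CcfMatrix, order: list[str]) -> np.ndarray:
    n = len(order)
    c = matrix.ccf.loc[order].to_numpy()
    s = matrix.se.loc[order].to_numpy()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(np.isnan(c[i]) | np.isnan(c[j]))
            if not shared.any():
                raise IncomparableError(
                    f"{order[i]} and {order[j]} share no samples")
            pooled = np.sqrt(s[i, shared] ** 2 + s[j, shared] ** 2)
            z = np.abs(c[i, shared] - c[j, shared]) / np.maximum(
                pooled, _SE_FLOOR)
            d[i, j] = d[j, i] = z.max()
    return d


def cluster_mutations(matrix: CcfMatrix,
                      z_threshold: float | None = None,
                      config: PipelineConfig = DEFAULT_CONFIG,
                      ) -> list[MutationCluster]:
    """Average-linkage agglomeration on the worst-sample z distance.

    Merging proceeds greedily on the smallest linkage and halts when the
    minimum inter-cluster linkage reaches ``z_threshold``; ties break on the
    smallest member mutation id, so the result is independent of input row
    order. Clusters are returned ordered by descending mean centroid CCF and
    labelled cl00, cl01, ...
    """
    if z_threshold is None:
        z_threshold = config.z_threshold
    order = sorted(matrix.mutations)  # canonical internal ordering
    if not order:
        return []
    if len(order) == 1:
        clusters = [[order[0]]]
    else:
        d = _pair_distance_matrix(matrix, order)
        groups: list[list[int]] = [[i] for i in range(len(order))]
        link = d.astype(float).copy()
        np.fill_diagonal(link, np.inf)
        sizes = np.ones(len(order))
        active = list(range(len(order)))
        while len(active) > 1:
            best = None
            for ai in range(len(active)):
                for aj in range(ai + 1, len(active)):
                    i, j = active[ai], active[aj]
                    key = (link[i, j], order[min(groups[i][0], groups[j][0])],
                           order[max(groups[i][0], groups[j][0])])
                    if best is None or key < best[0]:
                        best = (key, i, j)
            (dist, *_), i, j = best
            if dist >= z_threshold:
                break
            # average linkage update: weighted by group sizes
            for k in active:
                if k in (i, j):
                    continue
                link[i, k] = link[k, i] = (
                    sizes[i] * link[i, k] + sizes[j] * link[j, k]
                ) / (sizes[i] + sizes[j])
            groups[i] = sorted(groups[i] + groups[j])
            sizes[i] += sizes[j]
            active.remove(j)
        member_sets = [sorted(order[k] for k in groups[i]) for i in active]
        clusters = member_sets

    built = []
    for members in clusters:
        centroid, se = _centroid(members, matrix)
        built.append(MutationCluster("tmp", members, centroid, se))
    built.sort(key=lambda c: (-np.nanmean(c.centroid.to_numpy(dtype=float)),
                              c.members[0]))
    for k, cl in enumerate(built):
        cl.cluster_id = f"cl{k:02d}"
    return built


def _centroid(members: list[str], matrix: CcfMatrix,
              ) -> tuple[pd.Series, pd.Series]:
    c = matrix.ccf.loc[members]
    s = matrix.se.loc[members]
    w = 1.0 / np.maximum(s ** 2, _SE_FLOOR ** 2)
    w = w.where(c.notna())
    wsum = w.sum(axis=0, min_count=1)
    centroid = (c * w).sum(axis=0, min_count=1) / wsum
    se = np.sqrt(1.0 / wsum)
    return centroid, se


def cluster_centroids(clusters: list[MutationCluster], matrix: CcfMatrix,
                      ) -> pd.DataFrame:
    """Recompute precision-weighted centroid trajectories (clusters x samples)."""
    rows = {}
    for cl in clusters:
        centroid, se = _centroid(cl.members, matrix)
        cl.centroid, cl.centroid_se = centroid, se
        rows[cl.cluster_id] = centroid
    return pd.DataFrame(rows).T
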