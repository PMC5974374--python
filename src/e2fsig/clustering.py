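"""Agglomerative hierarchical clustering with perturbation robustness indices.

Samples are clustered by complete linkage on Euclidean distance; genes by
complete linkage on correlation distance (1 − Pearson r).  Cluster stability
is quantified by reclustering after adding i.i.d. Gaussian noise to every
matrix entry:

* the **R index** is the mean, over perturbations, of the proportion of
  sample pairs sharing an original cluster that still share a cluster after
  perturbation (1 = perfectly reproducible);
* the **D index** is the mean total number of discrepancies — additions plus
  omissions — between each original cluster and the perturbed cluster that
  best matches it (0 = no discrepancies).

Both indices depend on the chosen noise SD; the default is the median of the
per-gene standard deviations of the input matrix, which makes the indices
comparable across datasets of different overall variability.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .exceptions import ParameterError
from .io import ExpressionMatrix

__all__ = ["ClusterReport", "cluster_samples", "cluster_genes", "robustness_indices"]


@dataclass
class ClusterReport:
    """Result of a hierarchical clustering run.

    ``assignment`` maps each item (sample or gene) to a cluster id in
    ``1..k``; clusters are labeled by decreasing size (cluster 1 largest),
    ties broken by first-occurring member.
    """

    method: str
    metric: str
    k: int
    assignment: pd.Series
    sizes: dict = field(default_factory=dict)
    robustness: dict | None = None
    labels: pd.Series | None = None  # optional semantic labels (e.g. E2F-high/low)

    def __post_init__(self) -> None:
        counts = self.assignment.value_counts()
        self.sizes = {int(c): int(counts[c]) for c in sorted(counts.index)}
        if sum(self.sizes.values()) != len(self.assignment):
            raise ParameterError("cluster sizes do not cover all items")

    def members(self, cluster_id: int) -> list:
        return self.assignment.index[self.assignment == cluster_id].tolist()


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids so 1 = largest; ties by first occurrence."""
    ids, counts = np.unique(raw, return_counts=True)
    first_pos = {i: int(np.argmax(raw == i)) for i in ids}
    order = sorted(ids, key=lambda i: (-counts[list(ids).index(i)], first_pos[i]))
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[i] for i in raw])


def cluster_samples(matrix: ExpressionMatrix, k: int = 2) -> ClusterReport:
    """Complete-linkage AHC of samples on Euclidean distance."""
    n = matrix.shape[1]
    if k < 1 or k > n:
        raise ParameterError(f"k={k} outside 1..{n} samples")
    X = matrix.values.to_numpy().T  # samples x genes
    dup = pd.DataFrame(X).duplicated()
    if dup.any():
        warnings.warn("matrix contains identical sample columns")
    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    assignment = pd.Series(_relabel_by_size(raw), index=matrix.sample_ids, name="cluster")
    return ClusterReport(method="complete", metric="euclidean", k=k, assignment=assignment)


def cluster_genes(matrix: ExpressionMatrix, k: int = 2) -> ClusterReport:
    """Complete-linkage AHC of genes on correlation distance (1 − Pearson r).

    Zero-variance genes have undefined correlation and are excluded with a
    warning.
    """
    vals = matrix.values
    sds = vals.std(axis=1, ddof=0)
    if (sds == 0).any():
        dropped = sds.index[sds == 0].tolist()
        warnings.warn(f"excluding {len(dropped)} zero-variance gene(s): {dropped[:5]}")
        vals = vals.loc[sds > 0]
    n = vals.shape[0]
    if k < 1 or k > n:
        raise ParameterError(f"k={k} outside 1..{n} genes")
    Z = linkage(pdist(vals.to_numpy(), metric="correlation"), method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    assignment = pd.Series(_relabel_by_size(raw), index=vals.index, name="cluster")
    return ClusterReport(method="complete", metric="correlation", k=k, assignment=assignment)


def _pair_coclustering(labels: np.ndarray) -> np.ndarray:
    """Boolean co-membership matrix (upper triangle used by callers)."""
    return labels[:, None] == labels[None, :]


def _match_greedy(orig: np.ndarray, pert: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Greedily match perturbed clusters to original clusters by maximal
    membership overlap; ties broken by smaller original then perturbed id."""
    overlap = np.zeros((k, k), dtype=int)
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            overlap[i - 1, j - 1] = int(np.sum((orig == i) & (pert == j)))
    pairs: list[tuple[int, int]] = []
    used_o: set = set()
    used_p: set = set()
    flat = sorted(
        ((overlap[i, j], i, j) for i in range(k) for j in range(k)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for _, i, j in flat:
        if i in used_o or j in used_p:
            continue
        pairs.append((i + 1, j + 1))
        used_o.add(i)
        used_p.add(j)
        if len(pairs) == k:
            break
    return pairs


def robustness_indices(
    matrix: ExpressionMatrix,
    k: int = 2,
    noise_sd: float | None = None,
    n_perturbations: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Gaussian-perturbation reclustering robustness of the sample clustering.

    Returns ``(R_index, D_index)``; R ∈ [0, 1], D ≥ 0.  Reproducible given
    ``(seed, n_perturbations)``.
    """
    if n_perturbations < 1:
        raise ParameterError("n_perturbations must be ≥ 1")
    if noise_sd is None:
        noise_sd = float(matrix.values.std(axis=1, ddof=1).median())
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be > 0")
    base = cluster_samples(matrix, k)
    orig = base.assignment.to_numpy()
    n = len(orig)
    co_orig = _pair_coclustering(orig)
    iu = np.triu_indices(n, 1)
    same_orig = co_orig[iu]
    n_same = int(same_orig.sum())
    rng = np.random.default_rng(seed)
    r_vals = np.empty(n_perturbations)
    d_vals = np.empty(n_perturbations)
    vals = matrix.values.to_numpy()
    for b in range(n_perturbations):
        noisy = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        # perturbed values may go non-positive even for linear input; declare
        # log2 to skip the positivity check — clustering only uses distances
        pert_m = ExpressionMatrix(
            pd.DataFrame(noisy, index=matrix.values.index, columns=matrix.values.columns),
            scale="log2",
        )
        pert = cluster_samples(pert_m, k).assignment.to_numpy()
        co_pert = _pair_coclustering(pert)[iu]
        r_vals[b] = float(np.sum(same_orig & co_pert)) / n_same if n_same else 1.0
        disc = 0
        for oi, pj in _match_greedy(orig, pert, k):
            in_o = orig == oi
            in_p = pert == pj
            disc += int(np.sum(in_o & ~in_p)) + int(np.sum(~in_o & in_p))
        d_vals[b] = disc
    return float(r_vals.mean()), float(d_vals.mean())
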