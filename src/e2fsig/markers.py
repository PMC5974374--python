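"""Differential-transcript selection between two sample groups.

The selection combines four criteria applied jointly to every gene:
a permutation Welch t-test raw p-value, its Benjamini-Hochberg FDR
adjustment, the Welch t score itself, and a signed linear fold change.
Defaults: raw p < 0.002, q < 0.05, t > 6 (up) / t ≤ −6 (down),
signed fold change > 1.2 (up) / ≤ −1.2 (down).

Scale handling: t statistics and permutations are computed on log2
intensities (variance-stabilised, as is standard for microarray data) while
fold changes are ratios of linear-scale group means, reported with the
signed convention (a gene 1.5-fold *down* has signed_fc = −1.5, i.e.
−meanB/meanA).  Both views are derived from the matrix's declared scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError
from .io import ExpressionMatrix

__all__ = [
    "MarkerThresholds",
    "welch_t",
    "permutation_p",
    "bh_adjust",
    "select_markers",
]


@dataclass(frozen=True)
class MarkerThresholds:
    """The four-criterion filter thresholds."""

    raw_p: float = 0.002
    fdr_q: float = 0.05
    t: float = 6.0
    fc: float = 1.2

    def __post_init__(self) -> None:
        if not (0 < self.raw_p < 1) or not (0 < self.fdr_q < 1):
            raise ParameterError("p/q thresholds must lie in (0,1)")
        if self.t <= 0 or self.fc < 1:
            raise ParameterError("t threshold must be > 0 and fc threshold ≥ 1")


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic for 2-D arrays (genes x samples).

    Sign convention: positive ⇒ higher in group A.  Degenerate rows (both
    groups zero variance): t = 0 when means equal, ±inf otherwise.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    zero = denom == 0
    if zero.any():
        t = np.where(zero & (ma == mb), 0.0, t)
        t = np.where(zero & (ma != mb), np.where(ma > mb, np.inf, -np.inf), t)
    return t


def welch_t(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Welch (unequal-variance) t statistic for one gene.

    Positive means higher in group A (the E2F-high / cluster-1 side by the
    pipeline's convention).
    """
    a = np.asarray(values_a, dtype=float)[None, :]
    b = np.asarray(values_b, dtype=float)[None, :]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ParameterError("welch_t needs ≥2 samples per group")
    return float(_welch_rows(a, b)[0])


def permutation_p(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the Welch t of one gene.

    p = (1 + #{permuted |t| ≥ observed |t|}) / (n_perm + 1); the +1
    smoothing keeps p strictly positive.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    if n_perm < 100:
        raise ParameterError("n_perm must be ≥ 100")
    pooled = np.concatenate([a, b])[None, :]
    obs = abs(welch_t(a, b))
    rng = np.random.default_rng(seed)
    na = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[1])
        t = _welch_rows(pooled[:, perm[:na]], pooled[:, perm[na:]])[0]
        if abs(t) >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _signed_fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Signed linear fold change: ratio if up in A, −reciprocal if down."""
    with np.errstate(divide="ignore"):
        up = mean_a / mean_b
        down = -mean_b / mean_a
    return np.where(mean_a >= mean_b, up, down)


def select_markers(
    matrix: ExpressionMatrix,
    group_a: list,
    group_b: list,
    thresholds: MarkerThresholds | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Apply the four-criterion differential filter to every gene.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Averaged (one column per sample) expression matrix, either scale.
    group_a, group_b : list of sample ids
        Group A is the reference "high" side: positive t ⇒ higher in A.
    thresholds : MarkerThresholds, optional
    n_perm : int
        Number of label permutations shared by all genes (a single set of
        permutations is drawn and applied to every gene row, which both
        vectorises the computation and mirrors array-tool practice).
    seed : int

    Returns
    -------
    (records, summary)
        ``records`` has one row per gene: group means (linear), t_score,
        raw_p, fdr_q, signed_fc, per-criterion passes, direction.
        ``summary`` counts up/down/total selected.
    """
    thr = thresholds or MarkerThresholds()
    if 1.0 / (n_perm + 1) >= thr.raw_p:
        import warnings

        warnings.warn(
            f"permutation p floor 1/{n_perm + 1} ≥ raw_p threshold {thr.raw_p}; "
            "no gene can pass — increase n_perm"
        )
    ids = set(matrix.sample_ids)
    for g, name in ((group_a, "group_a"), (group_b, "group_b")):
        if len(g) < 2:
            raise ParameterError(f"{name} needs ≥2 samples")
        missing = [s for s in g if s not in ids]
        if missing:
            raise ParameterError(f"{name} samples absent from matrix: {missing[:5]}")
    if set(group_a) & set(group_b):
        raise ParameterError("groups overlap")

    log2 = matrix.to_log2().values
    lin = matrix.to_linear().values
    A = log2[list(group_a)].to_numpy()
    B = log2[list(group_b)].to_numpy()
    t_obs = _welch_rows(A, B)

    pooled = np.concatenate([A, B], axis=1)
    na = len(group_a)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(pooled.shape[0], dtype=int)
    abs_obs = np.abs(t_obs) - 1e-12
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[1])
        t_p = _welch_rows(pooled[:, perm[:na]], pooled[:, perm[na:]])
        exceed += np.abs(t_p) >= abs_obs
    raw_p = (1 + exceed) / (n_perm + 1)
    fdr_q = bh_adjust(raw_p)

    mean_a = lin[list(group_a)].mean(axis=1).to_numpy()
    mean_b = lin[list(group_b)].mean(axis=1).to_numpy()
    fc = _signed_fc(mean_a, mean_b)

    pass_p = raw_p < thr.raw_p
    pass_q = fdr_q < thr.fdr_q
    up = pass_p & pass_q & (t_obs > thr.t) & (fc > thr.fc)
    down = pass_p & pass_q & (t_obs <= -thr.t) & (fc <= -thr.fc)
    direction = np.where(up, "up", np.where(down, "down", "none"))

    records = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t_score": t_obs,
            "raw_p": raw_p,
            "fdr_q": fdr_q,
            "signed_fc": fc,
            "pass_raw_p": pass_p,
            "pass_fdr_q": pass_q,
            "pass_t": (t_obs > thr.t) | (t_obs <= -thr.t),
            "pass_fc": (fc > thr.fc) | (fc <= -thr.fc),
            "direction": direction,
        }
    ).set_index("gene_id")
    summary = {
        "n_up": int(up.sum()),
        "n_down": int(down.sum()),
        "n_total": int(up.sum() + down.sum()),
        "thresholds": thr,
        "n_perm": n_perm,
        "seed": seed,
    }
    return records, summary
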