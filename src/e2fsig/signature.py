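"""The 24-gene E2F ratio-median signature: normalization, scoring, classification.

The score is built in three steps, all on *linear-scale* expression:

1. **Sum-to-100 normalization.**  For each signature gene, the expression
   values across the cohort are rescaled so they sum to 100 — each value
   becomes the gene's percentage share contributed by that sample.  This
   makes up- and down-regulated genes directly comparable regardless of
   absolute intensity.
2. **Ratio matrix.**  For each sample, every (normalized up-gene) /
   (normalized down-gene) pair forms a ratio: with the full bundled
   signature of 11 up and 13 down genes, 11 × 13 = 143 ratios per sample.
3. **Median rule.**  A sample is called **E2F-high** when the median ratio
   exceeds 1, **E2F-low** when it is below 1 (a median of exactly 1 is
   "indeterminate").

Missing markers (e.g. a platform lacking some transcripts) simply shrink the
ratio grid — a cohort lacking 3 of the 13 down genes yields 11 × 10 = 110
ratios — and are reported by name.  Note the score is cohort-relative:
normalization sums run over the cohort's samples, so adding or removing a
sample can shift every score.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterReport, cluster_samples
from .exceptions import ClassificationError, GMTFormatError, ParameterError
from .io import ExpressionMatrix, GeneSet, read_gmt, write_gmt

__all__ = [
    "SignatureDefinition",
    "SignatureResult",
    "bundled_signature",
    "normalize_sum100",
    "ratio_median",
    "classify",
    "supervised_cluster",
]

LABEL_HIGH = "E2F-high"
LABEL_LOW = "E2F-low"
LABEL_TIE = "indeterminate"


@dataclass(frozen=True)
class SignatureDefinition:
    """Disjoint ordered lists of up- and down-regulated marker genes."""

    name: str
    up_genes: tuple
    down_genes: tuple

    def __post_init__(self) -> None:
        up, down = tuple(self.up_genes), tuple(self.down_genes)
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", down)
        if not up or not down:
            raise GMTFormatError("signature needs non-empty up and down lists")
        if len(set(up)) != len(up) or len(set(down)) != len(down):
            raise GMTFormatError("duplicate genes within a signature list")
        if set(up) & set(down):
            raise GMTFormatError(f"up/down overlap: {sorted(set(up) & set(down))}")

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    @classmethod
    def from_gmt(cls, path: str | Path, name: str | None = None) -> "SignatureDefinition":
        """Load from a two-set GMT file (``<name>_UP`` and ``<name>_DN``)."""
        sets = {s.name: s for s in read_gmt(path)}
        ups = [k for k in sets if k.endswith("_UP")]
        dns = [k for k in sets if k.endswith("_DN")]
        if len(ups) != 1 or len(dns) != 1:
            raise GMTFormatError(
                f"signature GMT must contain exactly one *_UP and one *_DN set, got {sorted(sets)}"
            )
        base = ups[0][:-3]
        return cls(
            name=name or base,
            up_genes=tuple(sets[ups[0]].members),
            down_genes=tuple(sets[dns[0]].members),
        )

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(
            [
                GeneSet(f"{self.name}_UP", "up-regulated signature genes", list(self.up_genes)),
                GeneSet(f"{self.name}_DN", "down-regulated signature genes", list(self.down_genes)),
            ],
            path,
        )


def bundled_signature() -> SignatureDefinition:
    """The bundled 24-gene signature (11 up, 13 down)."""
    ref = resources.files("e2fsig.data") / "e2f24.gmt"
    with resources.as_file(ref) as p:
        return SignatureDefinition.from_gmt(p, name="E2F24")


@dataclass
class SignatureResult:
    """Per-sample scores and cohort-level classification summary.

    ``scores`` columns: median_ratio, n_ratios, n_dropped_ratios, label.
    """

    signature: SignatureDefinition
    scores: pd.DataFrame
    missing_up: list = field(default_factory=list)
    missing_down: list = field(default_factory=list)
    label_counts: dict = field(default_factory=dict)
    confusion: pd.DataFrame | None = None
    false_positives: int | None = None
    false_negatives: int | None = None

    @property
    def n_missing(self) -> int:
        return len(self.missing_up) + len(self.missing_down)

    def summary(self) -> str:
        lines = [
            f"Signature: {self.signature.name} "
            f"({len(self.signature.up_genes)} up / {len(self.signature.down_genes)} down)",
            f"Samples scored: {len(self.scores)}",
            f"Missing markers: {self.n_missing} "
            f"(up: {self.missing_up or '-'}; down: {self.missing_down or '-'})",
            "Labels: " + ", ".join(f"{k}={v}" for k, v in sorted(self.label_counts.items())),
        ]
        if self.false_positives is not None:
            lines.append(
                f"vs reference: {self.false_positives} false positives, "
                f"{self.false_negatives} false negatives"
            )
        return "\n".join(lines)


def normalize_sum100(matrix: ExpressionMatrix, genes=None) -> tuple[pd.DataFrame, list]:
    """Scale each (retained) gene row so its values sum to 100 across samples.

    Returns ``(normalized, excluded)`` where ``excluded`` lists genes whose
    row sum was not strictly positive.  Input must be linear scale.
    """
    if matrix.scale != "linear":
        raise ParameterError("sum-to-100 normalization requires linear-scale input; convert first")
    vals = matrix.values if genes is None else matrix.subset_genes(genes).values
    if vals.shape[1] < 2:
        raise ParameterError("normalization needs ≥2 samples")
    sums = vals.sum(axis=1)
    excluded = sums.index[sums <= 0].tolist()
    kept = vals.loc[sums > 0]
    return kept.mul(100.0 / sums[sums > 0], axis=0), excluded


def ratio_median(
    normalized: pd.DataFrame, signature: SignatureDefinition, sample
) -> tuple[float, int, int]:
    """Median of all up/down ratios for one sample of a normalized matrix.

    Returns ``(median, n_used, n_dropped)``; ratios with a zero down-gene
    value are dropped (and counted), and an all-dropped sample raises.
    """
    up = [g for g in signature.up_genes if g in normalized.index]
    down = [g for g in signature.down_genes if g in normalized.index]
    if not up or not down:
        raise ClassificationError(
            f"signature {signature.name!r}: no up or no down genes present in matrix"
        )
    u = normalized.loc[up, sample].to_numpy(dtype=float)
    d = normalized.loc[down, sample].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.ravel(u[:, None] / d[None, :])
    ok = np.isfinite(ratios)
    n_dropped = int((~ok).sum())
    if not ok.any():
        raise ClassificationError(f"sample {sample!r}: every up/down ratio undefined")
    return float(np.median(ratios[ok])), int(ok.sum()), n_dropped


def classify(
    matrix: ExpressionMatrix,
    signature: SignatureDefinition | None = None,
    reference_labels: pd.Series | None = None,
) -> SignatureResult:
    """Score and label every sample of a cohort with the ratio-median rule.

    ``matrix`` may be linear or log2 (converted internally); its gene
    universe may lack signature genes, which are reported as missing.  When
    ``reference_labels`` (values ``E2F-high``/``E2F-low``) are given, a 2x2
    confusion table with false-positive/-negative counts is attached
    (high = positive class).
    """
    sig = signature or bundled_signature()
    lin = matrix.to_linear()
    present = set(lin.gene_ids)
    missing_up = [g for g in sig.up_genes if g not in present]
    missing_down = [g for g in sig.down_genes if g not in present]
    if len(missing_up) == len(sig.up_genes) or len(missing_down) == len(sig.down_genes):
        raise ClassificationError(
            f"signature {sig.name!r}: all up or all down markers missing from matrix"
        )
    sig_genes = list(sig.up_genes) + list(sig.down_genes)
    normalized, excluded = normalize_sum100(lin, genes=sig_genes)
    rows = []
    for s in lin.sample_ids:
        med, n_used, n_drop = ratio_median(normalized, sig, s)
        label = LABEL_HIGH if med > 1 else LABEL_LOW if med < 1 else LABEL_TIE
        rows.append((s, med, n_used, n_drop, label))
    scores = pd.DataFrame(
        rows, columns=["sample_id", "median_ratio", "n_ratios", "n_dropped_ratios", "label"]
    ).set_index("sample_id")
    result = SignatureResult(
        signature=sig,
        scores=scores,
        missing_up=missing_up + [g for g in excluded if g in sig.up_genes],
        missing_down=missing_down + [g for g in excluded if g in sig.down_genes],
        label_counts=scores["label"].value_counts().to_dict(),
    )
    if reference_labels is not None:
        ref = reference_labels.reindex(scores.index)
        pred = scores["label"]
        tab = pd.crosstab(
            pred, ref, rownames=["predicted"], colnames=["reference"], dropna=False
        )
        result.confusion = tab
        result.false_positives = int(((pred == LABEL_HIGH) & (ref == LABEL_LOW)).sum())
        result.false_negatives = int(((pred == LABEL_LOW) & (ref == LABEL_HIGH)).sum())
    return result


def supervised_cluster(
    matrix: ExpressionMatrix, gene_set: GeneSet, k: int = 2
) -> ClusterReport:
    """AHC of samples restricted to a gene set, oriented by expression level.

    The matrix is restricted to the gene set's members and clustered exactly
    as in unsupervised analysis; the cluster whose samples have the higher
    mean expression of the set's members is labeled ``E2F-high``, the other
    ``E2F-low`` (for k = 2; higher k gets rank labels).
    """
    import warnings as _warnings

    present = [g for g in gene_set.members if g in set(matrix.gene_ids)]
    absent = [g for g in gene_set.members if g not in set(matrix.gene_ids)]
    if len(present) < 2:
        raise ParameterError(
            f"gene set {gene_set.name!r}: fewer than 2 members present in matrix"
        )
    if absent:
        _warnings.warn(
            f"gene set {gene_set.name!r}: {len(absent)} member(s) absent: {absent[:5]}"
        )
    sub = matrix.subset_genes(present)
    report = cluster_samples(sub, k=k)
    means = sub.values.mean(axis=0)
    cluster_mean = {
        c: float(means[report.members(c)].mean()) for c in report.sizes
    }
    order = sorted(cluster_mean, key=cluster_mean.get, reverse=True)
    if k == 2:
        label_of = {order[0]: LABEL_HIGH, order[1]: LABEL_LOW}
    else:
        label_of = {c: f"E2F-rank{i + 1}" for i, c in enumerate(order)}
    report.labels = report.assignment.map(label_of)
    report.labels.name = "label"
    return report
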