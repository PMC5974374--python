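"""Expression-matrix, gene-set and sample-annotation I/O.

The on-disk formats are deliberately plain: tab-separated text for matrices
and annotations (UTF-8, ``.`` decimal), standard GMT for gene sets.  Readers
fail fast — duplicate identifiers, missing values or non-numeric cells raise
:class:`~e2fsig.exceptions.MatrixFormatError` naming the offending row or
column — because every downstream stage assumes a complete positive matrix.

Technical-duplicate handling follows standard microarray practice: each
patient is hybridised in duplicate, replicate concordance is checked by
pairwise Pearson correlation, and the per-sample mean of the duplicates (on
the matrix's declared scale) feeds all further analysis.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import GMTFormatError, MatrixFormatError, PairingError

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "read_matrix",
    "write_matrix",
    "average_duplicates",
    "infer_replicate_pairing",
    "replicate_correlation",
    "read_gmt",
    "write_gmt",
    "read_samples",
    "write_samples",
    "validate_samples",
]

_SCALES = ("linear", "log2")


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression table with a declared intensity scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as rows (index = gene IDs), samples as columns.  No missing
        values; strictly positive when ``scale="linear"``.
    scale : {"linear", "log2"}
        Whether ``values`` holds linear intensities or their log2.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise MatrixFormatError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene IDs: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample IDs: {dups[:5]}")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise MatrixFormatError(f"missing values in columns {bad[:5]}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise MatrixFormatError("non-numeric cells in expression matrix")
        if self.scale == "linear" and (self.values.values <= 0).any():
            gene = self.values.index[(self.values.values <= 0).any(axis=1)][0]
            raise MatrixFormatError(
                f"linear-scale matrix must be strictly positive; offending gene {gene!r}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.values), scale="linear")

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values), scale="log2")

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in matrix order); absent genes ignored."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], scale=self.scale)


@dataclass
class GeneSet:
    """A named gene set (GMT record)."""

    name: str
    description: str = ""
    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise GMTFormatError("gene set must have a name")
        if not self.members:
            raise GMTFormatError(f"gene set {self.name!r} has no members")
        seen: dict = {}
        for m in self.members:
            if m in seen:
                warnings.warn(f"duplicate member {m!r} in gene set {self.name!r} collapsed")
            seen[m] = None
        self.members = list(seen)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene IDs, header sample IDs)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise MatrixFormatError(f"{path.name}: duplicate sample IDs in header: {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for j, col in enumerate(df.columns):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[~df[col].map(lambda v: isinstance(v, (int, float)))].tolist()
            raise MatrixFormatError(
                f"{path.name}: non-numeric cell in column {col!r} (e.g. gene {bad[:1]})"
            )
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)]
        # +2: one for header line, one for 1-based numbering
        lineno = int(df.index.get_loc(rows[0])) + 2
        raise MatrixFormatError(f"{path.name}: missing value at gene {rows[0]!r} (line {lineno})")
    return ExpressionMatrix(df, scale=scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips through :func:`read_matrix`."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")


# ---------------------------------------------------------------------------
# technical duplicates
# ---------------------------------------------------------------------------

_REP_RE = re.compile(r"^(?P<sample>.+)_rep\d+$")


def infer_replicate_pairing(matrix: ExpressionMatrix) -> dict:
    """Infer column→sample pairing from ``<sample>_rep<k>`` column names."""
    pairing: dict = {}
    for col in matrix.sample_ids:
        m = _REP_RE.match(str(col))
        if m is None:
            raise PairingError(f"column {col!r} does not match '<sample>_rep<k>'")
        pairing[col] = m.group("sample")
    return pairing


def average_duplicates(matrix: ExpressionMatrix, pairing: Mapping | None = None) -> ExpressionMatrix:
    """Collapse technical replicates to one column per sample.

    The replicate mean is taken on the matrix's *declared* scale; gene order
    is preserved and samples appear in first-replicate order.  Re-applying
    with identity pairing is a no-op.
    """
    if pairing is None:
        pairing = infer_replicate_pairing(matrix)
    unassigned = [c for c in matrix.sample_ids if c not in pairing]
    if unassigned:
        raise PairingError(f"replicate columns not assigned to a sample: {unassigned[:5]}")
    order: list = []
    groups: dict = {}
    for col in matrix.sample_ids:
        s = pairing[col]
        if s not in groups:
            groups[s] = []
            order.append(s)
        groups[s].append(col)
    out = pd.DataFrame(
        {s: matrix.values[groups[s]].mean(axis=1) for s in order},
        index=matrix.values.index,
    )
    return ExpressionMatrix(out, scale=matrix.scale)


def replicate_correlation(
    matrix: ExpressionMatrix, pairing: Mapping | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Replicate-concordance QC.

    Returns ``(per_sample_r, corr)``: Pearson r between the two replicates of
    each sample, and the full column-by-column correlation matrix (symmetric,
    unit diagonal).  Raises for zero-variance columns, where Pearson r is
    undefined.
    """
    if pairing is None:
        pairing = infer_replicate_pairing(matrix)
    if matrix.shape[0] < 3:
        raise MatrixFormatError("replicate correlation needs at least 3 genes")
    sds = matrix.values.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()
        raise MatrixFormatError(f"zero-variance column(s), correlation undefined: {bad[:5]}")
    corr = matrix.values.corr(method="pearson")
    reps: dict = {}
    for col, s in pairing.items():
        reps.setdefault(s, []).append(col)
    out = {}
    for s, cols in reps.items():
        if len(cols) != 2:
            raise PairingError(f"sample {s!r} has {len(cols)} replicates; exactly 2 required")
        out[s] = float(corr.loc[cols[0], cols[1]])
    return pd.Series(out, name="pearson_r"), corr


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path.name}:{lineno}: GMT line needs name, description and ≥1 member"
                )
            members = [f for f in fields[2:] if f]
            if not members:
                raise GMTFormatError(f"{path.name}:{lineno}: gene set {fields[0]!r} has no members")
            sets.append(GeneSet(name=fields[0], description=fields[1], members=members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------

_REQUIRED_SAMPLE_COLS = ("sample_id", "os_months", "os_event")


def validate_samples(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table (survival endpoints + labels)."""
    for col in _REQUIRED_SAMPLE_COLS:
        if col not in table.columns:
            raise MatrixFormatError(f"sample table missing required column {col!r}")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise MatrixFormatError(f"duplicate sample_id values: {dups[:5]}")
    for tcol, ecol in (("os_months", "os_event"), ("rfs_months", "rfs_event")):
        if tcol not in table.columns:
            continue
        if (table[tcol] < 0).any():
            raise MatrixFormatError(f"negative times in {tcol!r}")
        if not table[ecol].isin([0, 1]).all():
            raise MatrixFormatError(f"{ecol!r} must be 0/1")
    return table


def read_samples(path: str | Path) -> pd.DataFrame:
    return validate_samples(pd.read_csv(path, sep="\t"))


def write_samples(table: pd.DataFrame, path: str | Path) -> None:
    validate_samples(table).to_csv(path, sep="\t", index=False)
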