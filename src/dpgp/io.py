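"""Expression-matrix container, tab-delimited I/O and per-gene standardization.

The on-disk format is a plain TSV: first column gene identifiers, header row
of numeric time labels, empty or ``NA`` cells marking missing observations.
This is the format common expression-matrix exports produce and the one the
simulator writes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gp import DataError, TimeGrid

logger = logging.getLogger("dpgp")

NA_VALUES = ("", "NA", "NaN", "nan")
FLOAT_FORMAT = "%.6g"  # matrix and table output at 6 significant digits


@dataclass
class ExpressionMatrix:
    """P gene trajectories over a shared time grid.

    ``values`` is a P x T float array with NaN at missing cells; ``mask`` is
    True where a value is observed.  ``standardized`` records whether each
    gene has been z-scored over its observed entries.
    """

    gene_ids: np.ndarray
    grid: TimeGrid
    values: np.ndarray
    standardized: bool = False
    mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array")
        P, T = self.values.shape
        if self.gene_ids.shape != (P,):
            raise DataError("gene_ids length must match number of rows")
        if T != self.grid.T:
            raise DataError("number of columns must match the time grid")
        ids, counts = np.unique(self.gene_ids.astype(str), return_counts=True)
        dup = ids[counts > 1]
        if dup.size:
            raise DataError(f"duplicate gene ids: {', '.join(map(str, dup[:5]))}")
        self.mask = np.isfinite(self.values)

    @property
    def P(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.grid.times)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.gene_ids.copy(), self.grid,
                                self.values.copy(), self.standardized)


def read_matrix(path, standardized: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    The header row must contain numeric time labels (scaled internally so the
    mean sampling interval is one unit); the first column holds unique gene
    ids; empty cells and ``NA`` are treated as missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(NA_VALUES),
                     keep_default_na=False)
    try:
        times = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: header row must contain numeric time labels "
                        f"(got {list(df.columns)[:5]})") from exc
    values = df.to_numpy(dtype=float)
    bad = ~(np.isfinite(values) | np.isnan(values))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DataError(f"{path}: non-numeric cell at line {r + 2}, column {c + 2}")
    dup = df.index[df.index.duplicated()].unique()
    if dup.size:
        lines = [str(int(np.flatnonzero(df.index == d)[-1]) + 2) for d in dup[:5]]
        raise DataError(f"{path}: duplicate gene ids {list(dup[:5])} (lines {', '.join(lines)})")
    return ExpressionMatrix(df.index.to_numpy(dtype=object), TimeGrid(times),
                            values, standardized=standardized)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix in the same TSV format ``read_matrix`` accepts."""
    df = matrix.to_dataframe()
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA",
              index_label="gene")


def standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene over its observed entries (population variance).

    Constant genes and genes with fewer than two observations are a hard
    error: silently rescaling them would corrupt the noise model, so callers
    are expected to pre-filter.  The offending ids are listed in the message.
    """
    values = matrix.values.copy()
    mask = matrix.mask
    nobs = mask.sum(axis=1)
    too_few = nobs < 2
    with np.errstate(invalid="ignore"):
        means = np.where(mask, values, 0.0).sum(axis=1) / np.maximum(nobs, 1)
        sq = np.where(mask, (values - means[:, None]) ** 2, 0.0).sum(axis=1)
        var = sq / np.maximum(nobs, 1)
    constant = (~too_few) & (var <= 0)
    if too_few.any() or constant.any():
        ids = matrix.gene_ids[too_few | constant]
        raise DataError("cannot standardize constant or under-observed genes: "
                        + ", ".join(map(str, ids[:10])))
    values = (values - means[:, None]) / np.sqrt(var)[:, None]
    out = replace(matrix, values=values, standardized=True)
    return out
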