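"""Expression-matrix / annotation IO and housekeeping-gene normalization.

Matrices are tab- or comma-separated text with a header row of marker names
and a leading ``sample_id`` column; values are copy-number-scale abundances.
Lines starting with ``#`` are treated as comments (pipeline outputs carry a
provenance header).  Normalization expresses each marker as log2 abundance
relative to the geometric mean of a set of housekeeping (reference)
transcripts, the standard reference-gene convention for relative mRNA
quantification:

    norm[s, m] = log2(copies[s, m] + pc) - mean_h log2(copies[s, h] + pc)

which is invariant to per-sample global scaling as the pseudocount ``pc``
becomes small relative to the counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


def _delimiter_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(path: str | Path, allow_negative: bool = False) -> pd.DataFrame:
    """Read a samples x markers matrix, validating ids and values.

    Raises :class:`ValueError` naming the offending row/column on duplicate
    sample or marker ids, missing cells, non-numeric cells, or negative
    values.  Pass ``allow_negative=True`` for matrices on the normalized
    (log2 relative abundance) scale, where negative values are expected.
    """
    sep = _delimiter_for(path)
    with open(path) as fh:  # pandas mangles duplicate header names; check raw
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(sep)[1:]
                dup = {m for m in header if header.count(m) > 1}
                if dup:
                    raise ValueError(f"duplicate marker columns: {sorted(dup)}")
                break
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    dup_markers = df.columns[df.columns.duplicated()].tolist()
    if dup_markers:
        raise ValueError(f"duplicate marker columns: {sorted(set(dup_markers))}")
    dup_samples = df.index[df.index.duplicated()].tolist()
    if dup_samples:
        raise ValueError(f"duplicate sample ids: {sorted(set(dup_samples))}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"missing or non-numeric cell at sample {df.index[r]!r}, "
            f"marker {df.columns[c]!r}"
        )
    neg = (values < 0) if not allow_negative else (values != values)
    if neg.to_numpy().any():
        r, c = np.argwhere(neg.to_numpy())[0]
        raise ValueError(
            f"negative value at sample {df.index[r]!r}, marker {df.columns[c]!r}"
        )
    values.index.name = "sample_id"
    values.columns.name = "marker"
    return values


def write_expression_matrix(
    matrix: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a matrix as TSV/CSV (12 significant digits, round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = matrix.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep=_delimiter_for(path), float_format="%.12g")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (sample_id, class, cohort_id, split)."""
    ann = pd.read_csv(path, sep=_delimiter_for(path), comment="#", dtype=str)
    required = {"sample_id", "class", "cohort_id", "split"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    dup = ann["sample_id"][ann["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample ids in annotation: {sorted(set(dup))}")
    multi = ann.groupby("cohort_id")["split"].nunique()
    bad = multi[multi > 1].index.tolist()
    if bad:
        raise ValueError(f"cohorts mapped to more than one split: {bad}")
    return ann


def write_annotation(
    annotation: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        annotation.to_csv(fh, sep=_delimiter_for(path), index=False)


class HousekeeperNormalizer(BaseEstimator, TransformerMixin):
    """Log2 relative-abundance normalization against housekeeping markers.

    Parameters
    ----------
    housekeepers : sequence of str
        Reference marker ids; must all be columns of the matrix (the assay
        reserves three, any non-empty set is accepted).
    pseudocount : float, default 1.0
        Added inside every log2 so the transform is defined at the detection
        floor; must be > 0.

    Attributes
    ----------
    housekeepers_ : list of str
        Validated reference set, in input order.
    n_features_in_ : int
    """

    def __init__(self, housekeepers: Sequence[str] = (), pseudocount: float = 1.0):
        self.housekeepers = housekeepers
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y=None) -> "HousekeeperNormalizer":
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        hks = [str(h) for h in self.housekeepers]
        if not hks:
            raise ValueError("at least one housekeeping marker is required")
        missing = [h for h in hks if h not in X.columns]
        if missing:
            raise ValueError(f"housekeepers absent from matrix: {missing}")
        self.housekeepers_ = hks
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the matrix on the log2 relative-abundance scale.

        Housekeeping columns are retained (they become small values centred
        on zero).
        """
        missing = [h for h in self.housekeepers_ if h not in X.columns]
        if missing:
            raise ValueError(f"housekeepers absent from matrix: {missing}")
        log2x = np.log2(X.astype(float) + self.pseudocount)
        reference = log2x[self.housekeepers_].mean(axis=1)
        return log2x.sub(reference, axis=0)


def normalize_to_housekeepers(
    matrix: pd.DataFrame,
    housekeepers: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Functional wrapper over :class:`HousekeeperNormalizer`."""
    return HousekeeperNormalizer(housekeepers, pseudocount).fit_transform(matrix)
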