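"""Data model and I/O for expression matrices with sample/feature metadata.

The canonical in-memory container is :class:`ExpressionDataset`, a thin
wrapper around a samples x features :class:`pandas.DataFrame` plus two
aligned metadata tables. Canonical orientation is samples in rows,
matching the AnnData convention of observations x variables; readers
normalize either input orientation to it.

Expression values are accepted on any numeric scale; all downstream
correlation-based steps are scale-sensitive, so inputs should already be
normalized (and, for counts, typically log-transformed) before ingestion.
Missing values are permitted at ingestion and must be removed by QC
filtering before network construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Orientation = Literal["samples", "features"]

_MISSING_MARKERS = {"", "na", "nan", "n/a", "null", "none"}


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = sorted(set(ids[ids.duplicated()].tolist()))
        raise ValueError(f"duplicate {what} identifiers: {dups}")


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with aligned metadata.

    Parameters
    ----------
    matrix
        DataFrame of shape (n_samples, n_features); index = sample ids,
        columns = feature ids. Values are floats; NaN marks missing.
    sample_meta
        Optional table indexed by sample id (aligned on construction).
    feature_meta
        Optional table indexed by feature id (aligned on construction).
    """

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.matrix, pd.DataFrame):
            self.matrix = pd.DataFrame(self.matrix)
        self.matrix.index = self.matrix.index.astype(str).str.strip()
        self.matrix.columns = self.matrix.columns.astype(str).str.strip()
        _check_unique(self.matrix.index, "sample")
        _check_unique(self.matrix.columns, "feature")
        self.matrix = self.matrix.astype(float)
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.matrix.index.copy())
        else:
            self.sample_meta = self.sample_meta.reindex(self.matrix.index)
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.matrix.columns.copy())
        else:
            self.feature_meta = self.feature_meta.reindex(self.matrix.columns)

    # -- basic properties -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.matrix.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    def has_missing(self) -> bool:
        return bool(self.matrix.isna().to_numpy().any())

    def require_complete(self, context: str = "this operation") -> None:
        """Raise if any value is missing; network ops never pairwise-delete."""
        if self.has_missing():
            n = int(self.matrix.isna().to_numpy().sum())
            raise ValueError(
                f"{context} requires a complete matrix but {n} values are "
                "missing; filter or drop incomplete features/samples first"
            )

    def subset(
        self,
        samples: list[str] | None = None,
        features: list[str] | None = None,
    ) -> "ExpressionDataset":
        mat = self.matrix
        if samples is not None:
            mat = mat.loc[samples]
        if features is not None:
            mat = mat[features]
        return ExpressionDataset(
            matrix=mat.copy(),
            sample_meta=self.sample_meta.reindex(mat.index),
            feature_meta=self.feature_meta.reindex(mat.columns),
        )

    def transpose(self) -> "ExpressionDataset":
        """Swap the sample and feature axes (metadata tables swap too)."""
        return ExpressionDataset(
            matrix=self.matrix.T.copy(),
            sample_meta=self.feature_meta.copy(),
            feature_meta=self.sample_meta.copy(),
        )

    # -- I/O ---------------------------------------------------------------
    def write(self, out_dir: str | Path, delimiter: str = "\t") -> None:
        """Write matrix + metadata tables as delimited text files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ext = "tsv" if delimiter == "\t" else "csv"
        self.matrix.to_csv(out / f"expression.{ext}", sep=delimiter, index_label="id")
        self.sample_meta.to_csv(out / f"sample_meta.{ext}", sep=delimiter, index_label="id")
        self.feature_meta.to_csv(out / f"feature_meta.{ext}", sep=delimiter, index_label="id")


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    orientation: Orientation = "samples",
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix into canonical orientation.

    The first column must hold row identifiers. With
    ``orientation="samples"`` rows are samples; with
    ``orientation="features"`` rows are features and the matrix is
    transposed into the canonical samples x features layout.

    Empty cells and the markers NA/NaN/N/A/null/none (case-insensitive)
    are recorded as missing, never as zero. A non-numeric cell raises a
    ``ValueError`` naming its row and column; duplicated identifiers
    raise listing the duplicates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if orientation not in ("samples", "features"):
        raise ValueError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    _check_unique(raw.index, "row")
    _check_unique(raw.columns, "column")

    def parse_cell(value: str, row: str, col: str) -> float:
        v = value.strip()
        if v.lower() in _MISSING_MARKERS:
            return np.nan
        try:
            return float(v)
        except ValueError:
            raise ValueError(
                f"non-numeric cell {value!r} at row {row!r}, column {col!r} of {path}"
            ) from None

    parsed = pd.DataFrame(
        [
            [parse_cell(raw.iat[i, j], raw.index[i], raw.columns[j]) for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
        dtype=float,
    )
    if orientation == "features":
        parsed = parsed.T
    return ExpressionDataset(matrix=parsed)


def read_h5ad(path: str | Path) -> ExpressionDataset:
    """Read an AnnData .h5ad file (obs -> samples, var -> features)."""
    import anndata as ad

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"h5ad file not found: {path}")
    adata = ad.read_h5ad(path)
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = X.toarray()
    matrix = pd.DataFrame(np.asarray(X, dtype=float), index=adata.obs_names, columns=adata.var_names)
    return ExpressionDataset(
        matrix=matrix,
        sample_meta=adata.obs.copy(),
        feature_meta=adata.var.copy(),
    )


def attach_metadata(
    ds: ExpressionDataset,
    table: pd.DataFrame,
    axis: Literal["sample", "feature"] = "sample",
) -> ExpressionDataset:
    """Attach a metadata table aligned by identifier on the chosen axis.

    Identifiers present in the table but not in the dataset are dropped
    with a warning; dataset identifiers absent from the table receive
    missing metadata. A table sharing no identifiers with the dataset is
    an error.
    """
    if axis not in ("sample", "feature"):
        raise ValueError(f"axis must be 'sample' or 'feature', got {axis!r}")
    table = table.copy()
    table.index = table.index.astype(str).str.strip()
    _check_unique(table.index, f"{axis} metadata")
    ids = pd.Index(ds.sample_ids if axis == "sample" else ds.feature_ids)
    overlap = table.index.intersection(ids)
    if len(overlap) == 0:
        raise ValueError(f"{axis} metadata table shares no identifiers with the dataset")
    extra = table.index.difference(ids)
    if len(extra) > 0:
        logger.warning(
            "dropping %d %s metadata rows with unknown identifiers (e.g. %s)",
            len(extra), axis, list(extra[:5]),
        )
    aligned = table.reindex(ids)
    if axis == "sample":
        return ExpressionDataset(matrix=ds.matrix.copy(), sample_meta=aligned, feature_meta=ds.feature_meta)
    return ExpressionDataset(matrix=ds.matrix.copy(), sample_meta=ds.sample_meta, feature_meta=aligned)
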