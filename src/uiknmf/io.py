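"""Reading, writing and preprocessing labeled nonnegative matrices.

TSV/CSV files carry row labels in the first column and sample labels in the
header; MatrixMarket (``.mtx``) files carry the values with label sidecars
``<stem>.rows`` and ``<stem>.cols`` (one label per line) next to them.
Validation happens on read: negative entries, empty rows/columns and
duplicate labels are rejected with their locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ArgumentError, EmptyResultError, ValidationError
from .matrix import TargetMatrix

__all__ = ["read_matrix", "write_matrix", "PreprocessConfig", "preprocess"]

logger = logging.getLogger("uiknmf")

_FORMATS = ("tsv", "csv", "mtx")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ArgumentError(f"cannot infer format from {path.name!r}; pass format= explicitly")


def _sidecars(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(".rows"), path.with_suffix(".cols")


def read_matrix(path: str | Path, format: str | None = None) -> TargetMatrix:
    """Read and validate a labeled nonnegative matrix.

    Raises :class:`~uiknmf.errors.ValidationError` (negative entries, empty
    rows/columns, duplicate labels, label-count mismatch) or a pandas/scipy
    parse error on malformed files.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ArgumentError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        if df.shape[1] == 0:
            raise ValidationError(f"{path.name}: no data columns after the label column")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValidationError(f"{path.name}: non-numeric entries ({exc})") from exc
        return TargetMatrix(values, list(map(str, df.index)), list(map(str, df.columns)))
    values = scipy.io.mmread(path)
    if scipy.sparse.issparse(values):
        values = values.toarray()
    rows_path, cols_path = _sidecars(path)
    for p in (rows_path, cols_path):
        if not p.exists():
            raise ArgumentError(f"missing label sidecar {p.name} next to {path.name}")
    row_labels = rows_path.read_text().splitlines()
    col_labels = cols_path.read_text().splitlines()
    return TargetMatrix(np.asarray(values, dtype=float), row_labels, col_labels)


def write_matrix(V: TargetMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix in the same layouts :func:`read_matrix` accepts."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        V.to_dataframe().to_csv(path, sep="\t" if fmt == "tsv" else ",")
        return
    if fmt != "mtx":
        raise ArgumentError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(V.values))
    rows_path, cols_path = _sidecars(path)
    rows_path.write_text("\n".join(V.row_labels) + "\n")
    cols_path.write_text("\n".join(V.col_labels) + "\n")


@dataclass(frozen=True)
class PreprocessConfig:
    """Expression-matrix preprocessing, applied in a fixed order.

    1. Drop features whose total count is below ``min_total_count``
       (low-quality features with inadequate reads).
    2. ``log2(x + pseudo_count)`` when ``log_transform``.
    3. Per-sample normalization when ``normalize_samples``: divide each
       column by its mean (``normalize_mode="divide"``, the default, keeps
       entries nonnegative) or subtract the column mean clamped at zero
       (``"subtract"``, with a warning — clamping loses information).
    4. Keep the ``variance_filter_keep`` highest-variance features.

    The order matters (filtering before the log changes which features pass)
    and is enforced; every step logs how many features survive.
    """

    log_transform: bool = False
    pseudo_count: float = 1.0
    min_total_count: float = 0.0
    normalize_samples: bool = False
    normalize_mode: str = "divide"
    variance_filter_keep: int | None = None

    def __post_init__(self) -> None:
        if self.pseudo_count < 0:
            raise ArgumentError("pseudo_count must be >= 0")
        if self.min_total_count < 0:
            raise ArgumentError("min_total_count must be >= 0")
        if self.normalize_mode not in ("divide", "subtract"):
            raise ArgumentError("normalize_mode must be 'divide' or 'subtract'")
        if self.variance_filter_keep is not None and self.variance_filter_keep < 1:
            raise ArgumentError("variance_filter_keep must be >= 1 when set")


def preprocess(V: TargetMatrix, cfg: PreprocessConfig) -> TargetMatrix:
    """Apply the configured steps in order; identity when all are off."""
    values = V.values.copy()
    row_labels = list(V.row_labels)

    if cfg.min_total_count > 0:
        keep = values.sum(axis=1) >= cfg.min_total_count
        values = values[keep]
        row_labels = [x for x, k in zip(row_labels, keep) if k]
        logger.info("preprocess: total-count filter kept %d/%d features", keep.sum(), keep.size)
        if values.shape[0] == 0:
            raise EmptyResultError("total-count filter removed every feature")

    if cfg.log_transform:
        values = np.log2(values + cfg.pseudo_count)
        logger.info("preprocess: log2(x + %g) applied", cfg.pseudo_count)

    if cfg.normalize_samples:
        means = values.mean(axis=0)
        if cfg.normalize_mode == "divide":
            if (means == 0).any():
                raise ValidationError("cannot divide by a zero column mean")
            values = values / means
        else:
            logger.warning("preprocess: subtract-mean normalization clamps negatives at 0")
            values = np.maximum(values - means, 0.0)
        logger.info("preprocess: per-sample %s-mean normalization applied", cfg.normalize_mode)

    if cfg.variance_filter_keep is not None:
        keep_n = cfg.variance_filter_keep
        if keep_n > values.shape[0]:
            raise ArgumentError(
                f"variance_filter_keep={keep_n} exceeds {values.shape[0]} remaining features"
            )
        variances = values.var(axis=1)
        # Stable top-k: sort by (-variance, original index) so ties keep file order.
        order = np.lexsort((np.arange(variances.size), -variances))[:keep_n]
        order.sort()
        values = values[order]
        row_labels = [row_labels[i] for i in order]
        logger.info("preprocess: variance filter kept %d features", keep_n)

    return TargetMatrix(values, row_labels, list(V.col_labels))
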