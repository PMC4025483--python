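"""Gene × timepoint expression matrices.

The container holds a nonnegative abundance matrix with one row per gene
and one column per developmental stage, the shape produced by staged
RNA-seq time courses (e.g. a 0–24 h embryonic series quantified in 2-h
bins).  Rows are keyed by unique gene identifiers and columns by ordered
stage labels such as ``"0-2h" … "22-24h"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression", "write_expression", "stage_labels_2h"]


def stage_labels_2h(n: int = 12) -> list[str]:
    """Ordered 2-hour stage labels ("0-2h", "2-4h", …)."""
    return [f"{2 * i}-{2 * i + 2}h" for i in range(n)]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative gene × timepoint abundance matrix.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    stage_labels
        Ordered timepoint names, one per column.
    values
        Array of shape ``(len(gene_ids), len(stage_labels))`` of finite,
        nonnegative abundances.
    """

    gene_ids: list[str]
    stage_labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", [str(g) for g in self.gene_ids])
        object.__setattr__(self, "stage_labels", [str(s) for s in self.stage_labels])
        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes × timepoints array")
        if len(self.gene_ids) != values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene IDs but {values.shape[0]} rows"
            )
        if len(self.stage_labels) != values.shape[1]:
            raise ValueError(
                f"{len(self.stage_labels)} stage labels but {values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if values.shape[1] < 2:
            raise ValueError("at least 2 timepoints required")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if np.any(values < 0):
            raise ValueError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.stage_labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(i) for i in frame.index],
            stage_labels=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene × timepoint table.

    The first column holds gene IDs and the header row holds stage labels.
    Tab-separated by default; ``.csv`` files use commas.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected ≥2 timepoint columns, got {frame.shape[1]}")
    return ExpressionMatrix.from_frame(frame)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id")
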