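"""Expression-matrix container shared by every stage of the pipeline.

Rows are probe sets (or genes), columns are samples, and a scale tag records
what the values mean: raw length-normalized abundances (``tpm``/``fpkm``),
log2 RMA-style intensities (``log2_intensity``), or values placed on the
common normalized scale (``normalized``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCALE_TAGS = ("tpm", "fpkm", "log2_intensity", "normalized")


@dataclass
class ExpressionMatrix:
    frame: pd.DataFrame
    scale_tag: str = "log2_intensity"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique()[:3]
            raise ValueError(f"duplicate row IDs, e.g. {list(dups)}")
        if self.frame.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        self.frame = self.frame.astype(float)

    @classmethod
    def from_arrays(cls, row_ids, col_ids, values, scale_tag) -> "ExpressionMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(row_ids), columns=list(col_ids)),
                   scale_tag)

    @property
    def row_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def col_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def subset_rows(self, row_ids) -> "ExpressionMatrix":
        missing = [r for r in row_ids if r not in self.frame.index]
        if missing:
            raise KeyError(
                f"{len(missing)} row ID(s) absent from matrix, e.g. {missing[:5]}"
            )
        return ExpressionMatrix(self.frame.loc[list(row_ids)], self.scale_tag)

    def subset_cols(self, col_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame[list(col_ids)], self.scale_tag)

    def with_values(self, values: np.ndarray, scale_tag: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.frame.index, columns=self.frame.columns),
            scale_tag or self.scale_tag,
        )

    def write_tsv(self, path: str | Path) -> None:
        """TSV with the ID column first; values at 10 significant digits."""
        out = self.frame.copy()
        out.index.name = "probe_set_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path, scale_tag: str) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index.name = None
        return cls(frame, scale_tag)


def hstack(left: ExpressionMatrix, right: ExpressionMatrix,
           scale_tag: str | None = None) -> ExpressionMatrix:
    """Column-concatenate two matrices after checking row agreement."""
    if left.row_ids != right.row_ids:
        raise ValueError("matrices have different row IDs; align rows first")
    frame = pd.concat([left.frame, right.frame], axis=1)
    return ExpressionMatrix(frame, scale_tag or left.scale_tag)
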