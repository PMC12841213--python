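"""Cell-type reference profiles used as the deconvolution design matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Cell types every reference must provide for the niche-calling stage.
CORE_CELL_TYPES = (
    "fibroblast",
    "keratinocyte",
    "T_gdT",
    "T_MAIT",
    "T_iNKT",
    "T_conv",
)

#: Reference columns counted towards the pan-T deconvolved fraction.
T_CELL_TYPES = ("T_gdT", "T_MAIT", "T_iNKT", "T_conv")


@dataclass
class ReferenceProfile:
    """Gene x cell-type matrix of mean expression per unit depth.

    ``markers`` optionally records, per cell type, the genes planted or
    curated as exclusive markers (used to derive signature sets).
    """

    genes: list[str]
    cell_types: list[str]
    mean_expr: np.ndarray  # (n_genes, n_cell_types), nonnegative
    markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_expr = np.asarray(self.mean_expr, dtype=float)
        if self.mean_expr.shape != (len(self.genes), len(self.cell_types)):
            raise ValidationError(
                "mean_expr shape does not match gene/cell-type lists"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols must be unique")
        if np.any(self.mean_expr < 0):
            raise ValidationError("reference expression must be nonnegative")
        zero_cols = np.flatnonzero(self.mean_expr.sum(axis=0) == 0)
        if zero_cols.size:
            bad = [self.cell_types[i] for i in zero_cols]
            raise ValidationError(f"all-zero reference columns: {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_expr, index=self.genes,
                            columns=self.cell_types)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   markers: dict[str, list[str]] | None = None
                   ) -> "ReferenceProfile":
        return cls(list(df.index), list(df.columns), df.to_numpy(float),
                   markers or {})


def write_reference(ref: ReferenceProfile, path: str | Path) -> None:
    ref.to_frame().to_csv(path, index_label="gene", float_format="%.10g")


def read_reference(path: str | Path) -> ReferenceProfile:
    df = pd.read_csv(path, index_col="gene")
    return ReferenceProfile.from_frame(df)
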