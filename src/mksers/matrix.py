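"""Expression-matrix container and I/O.

The matrix holds log-scale expression values (log2 microarray intensities or
log2 FPKM) as features x samples. Missing values are represented as NaN; all
downstream scoring treats NaN as "not observed". Linear-scale input must be
declared at load time and is log2(x+1)-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_tsv", "write_expression_tsv", "impute_missing"]


class AllMissingError(ValueError):
    """Raised when an operation needs at least one observed value and finds none."""


@dataclass
class ExpressionMatrix:
    """Log-scale feature x sample expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID (gene symbol or platform probe-set ID)
        with one column per sample. NaN marks missing entries.
    platform
        Free-text platform tag. Tags starting with ``"affy"`` switch signature
        resolution to probe-set matching.
    """

    values: pd.DataFrame
    platform: str = "generic"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_affymetrix(self) -> bool:
        return self.platform.lower().startswith("affy")

    def subset(self, features: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[features].copy(), platform=self.platform)


def impute_missing(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every missing entry by the global minimum of observed values.

    This is the lowest-value imputation used for sparse normalized microarray
    tables: absent measurements are assumed to sit at the detection floor.
    Observed entries are untouched; a matrix with no missing entries is
    returned unchanged (same object).
    """
    vals = matrix.values
    if not vals.isna().any().any():
        return matrix
    observed = vals.to_numpy()
    if np.all(np.isnan(observed)):
        raise AllMissingError("cannot impute an all-missing matrix")
    floor = np.nanmin(observed)
    return ExpressionMatrix(vals.fillna(floor), platform=matrix.platform)


def read_expression_tsv(
    path, platform: str = "generic", linear_scale: bool = False
) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column feature ID, header sample IDs).

    Empty cells and the strings ``NA``/``NaN`` are treated as missing. With
    ``linear_scale=True`` values are log2(x+1)-transformed on load.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if linear_scale:
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df, platform=platform)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")
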