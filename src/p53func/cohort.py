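"""Expression-cohort container shared by all analysis stages.

A cohort is a gene-by-sample numeric matrix carrying a *layer* tag
(``counts``, ``log2fpkm`` or ``tpm``) plus a sample sheet that assigns every
sample to one of the four study groups:

- ``NT``  adjacent normal tissue (assumed normal p53 function),
- ``WT``  tumors with wild-type TP53,
- ``MM``  tumors with TP53 missense / in-frame mutations,
- ``TM``  tumors with TP53 truncating mutations (assumed reduced function).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_LAYERS = ("counts", "log2fpkm", "tpm")
VALID_GROUPS = ("NT", "WT", "MM", "TM")


@dataclass
class ExpressionCohort:
    """Gene-by-sample expression matrix with a named layer and sample sheet.

    Parameters
    ----------
    matrix
        DataFrame with gene ids as index and sample ids as columns.
    layer
        One of ``counts``, ``log2fpkm``, ``tpm``.
    samples
        Sample sheet indexed by sample id with at least a ``group`` column
        (values in ``NT``/``WT``/``MM``/``TM``) and optionally a ``cohort``
        tag column.
    """

    matrix: pd.DataFrame
    layer: str
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        if self.matrix.shape[0] == 0 or self.matrix.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in expression matrix: {dup!r}")
        if not np.issubdtype(np.asarray(self.matrix).dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if self.samples is None:
            self.samples = pd.DataFrame(
                {"group": pd.Series(pd.NA, index=self.matrix.columns, dtype="object")}
            )
        missing = self.matrix.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples absent from sample sheet: {list(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.columns

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to one of the NT/WT/MM/TM groups."""
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        sheet = self.samples.loc[self.matrix.columns]
        return list(sheet.index[sheet["group"] == group])

    def subset_samples(self, sample_ids) -> "ExpressionCohort":
        """Restrict the cohort to the given samples (order preserved)."""
        ids = list(sample_ids)
        return ExpressionCohort(self.matrix[ids], self.layer, self.samples.loc[ids])

    def subset_genes(self, genes) -> "ExpressionCohort":
        return ExpressionCohort(self.matrix.loc[list(genes)], self.layer, self.samples)
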