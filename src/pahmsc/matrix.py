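"""Expression-matrix container and TSV interchange.

The central in-memory object of the pipeline is a genes x samples matrix of
log2 intensities together with a sample -> condition map.  On disk it is a
pair of plain TSV files: the matrix (first column ``gene_id``, header row of
sample ids) and a two-column sample map (``sample_id``, ``condition``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with condition labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Real-valued matrix, index = gene ids, columns = sample ids.
    condition_of : dict
        Maps every sample id to a condition label (e.g. ``"CON"``, ``"MCT"``).
    """

    values: pd.DataFrame
    condition_of: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unmapped = [s for s in self.values.columns if s not in self.condition_of]
        if unmapped:
            raise ValueError(f"samples without a condition label: {unmapped}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def conditions(self) -> list:
        """Condition labels in first-seen sample order."""
        seen: dict = {}
        for s in self.values.columns:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def samples_for(self, condition: str) -> list:
        out = [s for s in self.values.columns if self.condition_of[s] == condition]
        if not out:
            raise KeyError(f"no samples for condition {condition!r}")
        return out

    def subset(self, conditions) -> "ExpressionMatrix":
        cols = [s for c in conditions for s in self.samples_for(c)]
        return ExpressionMatrix(
            self.values[cols].copy(),
            {s: self.condition_of[s] for s in cols},
        )

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, matrix_path, sample_map_path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(matrix_path, sep="\t", float_format="%.6f")
        pd.DataFrame(
            {"sample_id": self.sample_ids,
             "condition": [self.condition_of[s] for s in self.sample_ids]}
        ).to_csv(sample_map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, sample_map_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values = values.astype(float)
        smap = pd.read_csv(sample_map_path, sep="\t")
        condition_of = dict(zip(smap["sample_id"].astype(str), smap["condition"]))
        return cls(values, condition_of)

    def copy_with(self, values: np.ndarray | pd.DataFrame) -> "ExpressionMatrix":
        if isinstance(values, np.ndarray):
            values = pd.DataFrame(values, index=self.values.index,
                                  columns=self.values.columns)
        return ExpressionMatrix(values, dict(self.condition_of))
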