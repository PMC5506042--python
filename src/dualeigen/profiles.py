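"""Expression-profile container shared by every analysis stage.

The central object is a log2-scale gene x sample matrix together with a
per-sample attribute table (diet, week of age, optional glucose/insulin
tolerance AUCs and a week-18 subgroup label).  Attributes are optional at
construction so that summarized chips can be represented before sample
metadata is joined, but any operation that needs a design factor will
refuse a profile without one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical attribute columns; extra columns are carried along untouched
FACTOR_COLUMNS = ("diet", "week", "gtt_auc", "itt_auc", "subgroup")

DIET_LEVELS = ("RC", "HFD")


@dataclass
class ExpressionProfile:
    """Log2 gene x sample expression matrix with sample attributes.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples), log2 scale, no missing entries.
        The index holds gene (probe-set) identifiers, the columns sample ids.
    attributes
        Optional DataFrame indexed by sample id.  When present it must cover
        every sample column of ``values``.
    """

    values: pd.DataFrame
    attributes: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated gene ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicated sample ids: {list(dups[:5])}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric cells")
        if np.isnan(arr).any():
            raise ValueError(
                "expression matrix contains missing entries; imputation is refused"
            )
        if self.attributes is not None:
            missing = self.values.columns.difference(self.attributes.index)
            if len(missing):
                raise ValueError(f"attribute rows missing for samples: {list(missing[:5])}")
            # align attribute order with the matrix columns
            self.attributes = self.attributes.loc[self.values.columns]

    # -- basic views ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- factor access -------------------------------------------------
    def factor(self, name: str) -> pd.Series:
        """Return one attribute column, failing loudly when absent."""
        if self.attributes is None:
            raise ValueError("profile has no sample attribute table")
        if name not in self.attributes.columns:
            raise KeyError(f"attribute {name!r} not present")
        return self.attributes[name]

    def subset_samples(self, sample_ids) -> "ExpressionProfile":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.samples)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)[:5]}")
        attrs = None if self.attributes is None else self.attributes.loc[sample_ids]
        return ExpressionProfile(self.values[sample_ids].copy(), attrs)

    def control_only(self, diet_level: str = "RC") -> "ExpressionProfile":
        """Keep only control (regular-chow) samples."""
        diet = self.factor("diet")
        keep = diet.index[diet == diet_level]
        if len(keep) == 0:
            raise ValueError(f"no samples with diet == {diet_level!r}")
        return self.subset_samples(keep)
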