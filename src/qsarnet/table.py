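"""The descriptor table: compounds x molecular descriptors plus one activity.

This is the central in-memory container of the package. Rows are compounds
(identified by unique string IDs), columns are named numeric molecular
descriptors (logP, surface areas, charge BCUTs, ... as exported by MOE- or
CDK-style tools), and the activity vector holds the regression target
(typically a log-scale potency such as pIC50 or LAC50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class DescriptorTable:
    """A compounds-by-descriptors matrix with an aligned activity vector.

    Parameters
    ----------
    descriptors
        DataFrame indexed by compound ID; one numeric column per descriptor.
    activity
        Series aligned with ``descriptors`` (same index, same order).
    activity_name
        Name of the activity column, e.g. ``"pIC50"``.
    """

    descriptors: pd.DataFrame
    activity: pd.Series
    activity_name: str = field(default="activity")

    def __post_init__(self) -> None:
        idx = self.descriptors.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate compound IDs: {dupes}")
        cols = self.descriptors.columns
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate descriptor names: {dupes}")
        if len(self.activity) != len(self.descriptors):
            raise ValidationError(
                f"activity length {len(self.activity)} does not match "
                f"row count {len(self.descriptors)}"
            )
        if not self.activity.index.equals(idx):
            self.activity = self.activity.reindex(idx)
        X = self.descriptors.to_numpy(dtype=float)
        if X.size and not np.isfinite(X).all():
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValidationError(
                f"non-finite descriptor value at compound "
                f"{idx[bad[0]]!r}, column {cols[bad[1]]!r}"
            )
        y = self.activity.to_numpy(dtype=float)
        if y.size and not np.isfinite(y).all():
            bad_id = idx[int(np.argwhere(~np.isfinite(y))[0])]
            raise ValidationError(f"non-finite activity for compound {bad_id!r}")

    # ------------------------------------------------------------------ views
    @property
    def compound_ids(self) -> list[str]:
        return [str(i) for i in self.descriptors.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.descriptors.columns]

    @property
    def m(self) -> int:
        """Number of compounds (rows)."""
        return len(self.descriptors)

    @property
    def n(self) -> int:
        """Number of descriptors (columns)."""
        return self.descriptors.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Descriptor matrix as a float array, shape (m, n)."""
        return self.descriptors.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Activity vector as a float array, shape (m,)."""
        return self.activity.to_numpy(dtype=float)

    # ------------------------------------------------------------ restriction
    def select_descriptors(self, names: list[str]) -> "DescriptorTable":
        """Restrict to the given descriptor columns (order as given)."""
        missing = [c for c in names if c not in self.descriptors.columns]
        if missing:
            raise ValidationError(f"unknown descriptor columns: {missing}")
        return DescriptorTable(
            self.descriptors.loc[:, list(names)].copy(),
            self.activity.copy(),
            self.activity_name,
        )

    def select_compounds(self, ids: list[str]) -> "DescriptorTable":
        """Restrict to the given compounds (order as given)."""
        missing = [c for c in ids if c not in self.descriptors.index]
        if missing:
            raise ValidationError(f"unknown compound IDs: {missing}")
        return DescriptorTable(
            self.descriptors.loc[list(ids)].copy(),
            self.activity.loc[list(ids)].copy(),
            self.activity_name,
        )

    def drop_compounds(self, ids: list[str]) -> "DescriptorTable":
        keep = [i for i in self.descriptors.index if i not in set(ids)]
        return self.select_compounds(keep)

    def copy(self) -> "DescriptorTable":
        return DescriptorTable(
            self.descriptors.copy(), self.activity.copy(), self.activity_name
        )

    def equals(self, other: "DescriptorTable") -> bool:
        return (
            self.activity_name == other.activity_name
            and self.descriptors.equals(other.descriptors)
            and self.activity.equals(other.activity)
        )
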