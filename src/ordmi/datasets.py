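"""Ordinal response datasets for two-group analyses."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OrdinalDataset", "REFERENCE", "FOCAL"]

REFERENCE = "reference"
FOCAL = "focal"


@dataclass(frozen=True)
class OrdinalDataset:
    """Integer item responses (coded 0..C-1) with group labels.

    Attributes
    ----------
    responses:
        (N, p) integer matrix; entry (i, j) is person i's response to item j.
    group_labels:
        length-N array of group names (usually "reference"/"focal").
    n_categories:
        number of response categories C shared by all items.
    """

    responses: np.ndarray
    group_labels: np.ndarray
    n_categories: int
    item_names: tuple = field(default=None)

    def __post_init__(self):
        r = np.asarray(self.responses, dtype=np.int64)
        g = np.asarray(self.group_labels)
        if r.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if g.shape[0] != r.shape[0]:
            raise ValueError("group_labels length must match rows of responses")
        if r.size and (r.min() < 0 or r.max() > self.n_categories - 1):
            raise ValueError("responses must lie in 0..C-1")
        object.__setattr__(self, "responses", r)
        object.__setattr__(self, "group_labels", g)
        if self.item_names is None:
            object.__setattr__(
                self, "item_names", tuple(f"item{j + 1}" for j in range(r.shape[1]))
            )

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def groups(self) -> tuple:
        seen = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def group(self, name) -> np.ndarray:
        """Response rows of one group."""
        return self.responses[self.group_labels == name]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=list(self.item_names))
        df["group"] = self.group_labels
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write one row per respondent plus a ``group`` column.

        A JSON sidecar records the category count so round-trips do not rely
        on every category being observed.
        """
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {"n_categories": int(self.n_categories)}
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path, group_col: str = "group", n_categories: int | None = None):
        path = Path(path)
        df = pd.read_csv(path)
        if group_col not in df.columns:
            raise ValueError(f"missing group column {group_col!r}")
        items = [c for c in df.columns if c != group_col]
        if n_categories is None:
            side = path.with_suffix(path.suffix + ".json")
            if side.exists():
                n_categories = int(json.loads(side.read_text())["n_categories"])
            else:
                n_categories = int(df[items].to_numpy().max()) + 1
        return cls(
            responses=df[items].to_numpy(dtype=np.int64),
            group_labels=df[group_col].to_numpy(),
            n_categories=n_categories,
            item_names=tuple(items),
        )
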