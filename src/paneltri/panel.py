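"""Tidy person x occasion panel container used by every analysis module.

A :class:`PanelDataset` holds two repeated composite scores (generically
``x`` and ``y``) for each person at integer occasions ``1..T``.  It is the
universal input of the model battery: SEM models consume its wide-format
sample moments, the multilevel regressions consume its long format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LONG_COLUMNS = ["person_id", "occasion", "x", "y"]


@dataclass
class PanelDataset:
    """Long-format panel of two repeated scores.

    Parameters
    ----------
    data
        DataFrame with columns ``person_id``, ``occasion`` (integers in
        ``1..T``), ``x`` and ``y`` (scale points).  ``(person_id, occasion)``
        pairs must be unique.
    """

    data: pd.DataFrame
    x_name: str = "x"
    y_name: str = "y"

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel is missing columns {missing}")
        if self.data.empty:
            raise ValueError("panel is empty")
        occ = self.data["occasion"].to_numpy()
        if not np.issubdtype(np.asarray(occ).dtype, np.integer):
            if not np.allclose(occ, np.round(occ)):
                raise ValueError("occasions must be integers")
            self.data = self.data.assign(occasion=np.round(occ).astype(int))
        if (self.data["occasion"] < 1).any():
            raise ValueError("occasions must be >= 1")
        if self.data.duplicated(["person_id", "occasion"]).any():
            raise ValueError("duplicate (person_id, occasion) rows")

    # -- basic properties -------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    @property
    def T(self) -> int:
        return int(self.data["occasion"].max())

    # -- conversions ------------------------------------------------------
    def to_wide(self, dropna: bool = False) -> pd.DataFrame:
        """Wide format with columns ``x1..xT, y1..yT`` indexed by person.

        With ``dropna=True`` only listwise-complete persons are kept.
        """
        T = self.T
        wide = self.data.pivot(index="person_id", columns="occasion", values=["x", "y"])
        cols = [(v, t) for v in ("x", "y") for t in range(1, T + 1)]
        wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
        wide.columns = [f"{v}{t}" for v, t in cols]
        if dropna:
            wide = wide.dropna()
        return wide

    @classmethod
    def from_wide(cls, wide: pd.DataFrame, T: int | None = None) -> "PanelDataset":
        """Build from a frame with columns ``x1..xT, y1..yT`` (id in index
        or an ``person_id`` column)."""
        wide = wide.copy()
        if "person_id" not in wide.columns:
            wide = wide.reset_index().rename(columns={wide.index.name or "index": "person_id"})
        if T is None:
            T = max(int(c[1:]) for c in wide.columns if c[:1] in ("x", "y") and c[1:].isdigit())
        rows = []
        for t in range(1, T + 1):
            sub = wide[["person_id", f"x{t}", f"y{t}"]].copy()
            sub.columns = ["person_id", "x", "y"]
            sub["occasion"] = t
            rows.append(sub)
        long = pd.concat(rows, ignore_index=True)[LONG_COLUMNS]
        long = long.dropna(subset=["x", "y"], how="all")
        return cls(long.sort_values(["person_id", "occasion"]).reset_index(drop=True))

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.data[LONG_COLUMNS].sort_values(["person_id", "occasion"])
        out.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path, layout: str = "long", id_col: str = "person_id",
                 time_col: str = "occasion", x_col: str = "x", y_col: str = "y") -> "PanelDataset":
        df = pd.read_csv(path)
        if layout == "long":
            df = df.rename(columns={id_col: "person_id", time_col: "occasion",
                                    x_col: "x", y_col: "y"})
            return cls(df[LONG_COLUMNS])
        if layout == "wide":
            df = df.rename(columns={id_col: "person_id"})
            return cls.from_wide(df)
        raise ValueError(f"unknown layout {layout!r}")
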