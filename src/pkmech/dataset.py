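"""Initial-velocity dataset container.

A :class:`VelocityDataset` wraps a pandas DataFrame with one row per
measured velocity and fixed column names:

    a_mM        varied or first substrate (PEP3- in the bisubstrate study)
    b_mM        co-substrate (ADP-Mg); equals the fixed level in
                single-substrate / inhibition designs
    i_mM        dead-end inhibitor (0 when absent)
    v           velocity (umol.min-1.mg-1)
    replicate   integer replicate index

``varied`` names the axis being titrated ("a", "b", or "i"-style designs
use "a" for the varied substrate), and ``design_meta`` carries free-text
provenance (generator settings, figure panel, file name).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["VelocityDataset", "COLUMNS"]

COLUMNS = ("a_mM", "b_mM", "i_mM", "v", "replicate")


@dataclass
class VelocityDataset:
    points: pd.DataFrame
    varied: str = "a"
    design_meta: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        pts = self.points
        for col in ("a_mM", "b_mM", "i_mM", "v"):
            if np.any(pts[col].to_numpy(dtype=float) < 0):
                raise ValueError(f"negative values in column {col!r}")
        if self.varied not in ("a", "b"):
            raise ValueError("varied must be 'a' or 'b'")
        if self.n_levels(self.varied) < 2:
            raise ValueError(
                "need at least 2 distinct levels of the varied axis"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def a(self) -> np.ndarray:
        return self.points["a_mM"].to_numpy(dtype=float)

    @property
    def b(self) -> np.ndarray:
        return self.points["b_mM"].to_numpy(dtype=float)

    @property
    def i(self) -> np.ndarray:
        return self.points["i_mM"].to_numpy(dtype=float)

    @property
    def v(self) -> np.ndarray:
        return self.points["v"].to_numpy(dtype=float)

    @property
    def s(self) -> np.ndarray:
        """Varied-substrate concentrations."""
        return self.a if self.varied == "a" else self.b

    @property
    def cosubstrate(self) -> np.ndarray:
        return self.b if self.varied == "a" else self.a

    def n_levels(self, axis: str) -> int:
        col = {"a": "a_mM", "b": "b_mM", "i": "i_mM"}[axis]
        return int(self.points[col].nunique())

    def __len__(self) -> int:
        return len(self.points)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        a: Iterable[float],
        b: Iterable[float],
        i: Iterable[float],
        v: Iterable[float],
        replicate: Iterable[int] | None = None,
        varied: str = "a",
        design_meta: str = "",
    ) -> "VelocityDataset":
        a = np.asarray(list(a), dtype=float)
        if replicate is None:
            replicate = np.zeros(len(a), dtype=int)
        df = pd.DataFrame(
            {
                "a_mM": a,
                "b_mM": np.asarray(list(b), dtype=float),
                "i_mM": np.asarray(list(i), dtype=float),
                "v": np.asarray(list(v), dtype=float),
                "replicate": np.asarray(list(replicate), dtype=int),
            }
        )
        return cls(df, varied=varied, design_meta=design_meta)

    @classmethod
    def read_table(
        cls, path: str | Path, varied: str = "a", design_meta: str | None = None
    ) -> "VelocityDataset":
        """Read a delimited text table with the standard header columns."""
        df = pd.read_csv(path, sep=None, engine="python")
        if "i_mM" not in df.columns:
            df["i_mM"] = 0.0
        if "replicate" not in df.columns:
            df["replicate"] = 0
        return cls(
            df[list(COLUMNS)],
            varied=varied,
            design_meta=design_meta if design_meta is not None else str(path),
        )

    def write_table(self, path: str | Path) -> None:
        self.points.to_csv(path, sep="\t", index=False)
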