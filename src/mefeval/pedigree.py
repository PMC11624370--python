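"""Pedigree container and validation.

A pedigree is a table of animals with integer ids, parent links (0 denotes an
unknown parent), birth year, sex and a genotyped flag.  It is the backbone
for the numerator relationship matrix A, its sparse inverse, the combined
relationship H, and for gene-dropping simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = 0

COLUMNS = ["animal", "sire", "dam", "birth_year", "sex", "genotyped"]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, bad parent link, ...)."""


@dataclass
class PedigreeTable:
    """Pedigree backed by a pandas DataFrame with columns
    animal, sire, dam, birth_year, sex ('M'/'F'), genotyped (bool)."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in ("animal", "sire", "dam") if c not in df.columns]
        if missing:
            raise PedigreeError(f"pedigree missing columns: {missing}")
        if "birth_year" not in df.columns:
            df["birth_year"] = 0
        if "sex" not in df.columns:
            df["sex"] = "F"
        if "genotyped" not in df.columns:
            df["genotyped"] = False
        for c in ("animal", "sire", "dam", "birth_year"):
            df[c] = df[c].astype(np.int64)
        df["genotyped"] = df["genotyped"].astype(bool)
        df = df[COLUMNS].reset_index(drop=True)
        if df["animal"].duplicated().any():
            raise PedigreeError("duplicate animal ids")
        if (df["animal"] == UNKNOWN).any():
            raise PedigreeError("animal id 0 is reserved for unknown parents")
        known = set(df["animal"])
        for col in ("sire", "dam"):
            bad = df.loc[(df[col] != UNKNOWN) & (~df[col].isin(known)), col]
            if len(bad):
                raise PedigreeError(f"{col} ids not in pedigree: {sorted(set(bad))[:5]}")
        self.df = df
        self._validate()

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].to_numpy()

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.df.loc[self.df["genotyped"], "animal"].to_numpy()

    def index_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` in the (sorted) pedigree order."""
        pos = pd.Series(np.arange(len(self.df)), index=self.df["animal"])
        return pos.loc[np.asarray(ids)].to_numpy()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based positional sire/dam indices; -1 for unknown."""
        pos = pd.Series(np.arange(len(self.df)), index=self.df["animal"])
        out = []
        for col in ("sire", "dam"):
            p = self.df[col].to_numpy()
            idx = np.full(len(p), -1, dtype=np.int64)
            m = p != UNKNOWN
            idx[m] = pos.loc[p[m]].to_numpy()
            out.append(idx)
        return out[0], out[1]

    # -- validation and ordering -------------------------------------------
    def _validate(self) -> None:
        df = self.df
        pos = pd.Series(np.arange(len(df)), index=df["animal"])
        sires = df.loc[df["sire"] != UNKNOWN, "sire"].unique()
        dams = df.loc[df["dam"] != UNKNOWN, "dam"].unique()
        sex = df.set_index("animal")["sex"]
        bad_sires = [s for s in sires if sex.loc[s] == "F"]
        bad_dams = [d for d in dams if sex.loc[d] == "M"]
        if bad_sires or bad_dams:
            raise PedigreeError(
                f"sex inconsistent with parent role: sires {bad_sires[:5]}, dams {bad_dams[:5]}"
            )
        if set(sires) & set(dams):
            raise PedigreeError("an animal appears as both sire and dam")
        # acyclicity via Kahn's algorithm on parent->offspring edges
        si, di = self.parent_indices()
        n = len(df)
        n_par = (si >= 0).astype(int) + (di >= 0).astype(int)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if si[i] >= 0:
                children[si[i]].append(i)
            if di[i] >= 0:
                children[di[i]].append(i)
        order = [i for i in range(n) if n_par[i] == 0]
        remaining = n_par.copy()
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for c in children[i]:
                remaining[c] -= 1
                if remaining[c] == 0:
                    order.append(c)
        if len(order) != n:
            raise PedigreeError("pedigree contains a cycle")
        self._topo_order = np.array(order, dtype=np.int64)
        by = df["birth_year"].to_numpy()
        for i in range(n):
            for p in (si[i], di[i]):
                if p >= 0 and by[p] > by[i]:
                    raise PedigreeError(
                        f"parent {df['animal'].iloc[p]} born after offspring {df['animal'].iloc[i]}"
                    )

    def is_sorted(self) -> bool:
        si, di = self.parent_indices()
        idx = np.arange(len(self.df))
        return bool(np.all(si < idx) and np.all(di < idx))

    def sorted(self) -> "PedigreeTable":
        """Topologically sorted copy (parents precede offspring)."""
        if self.is_sorted():
            return self
        return PedigreeTable(self.df.iloc[self._topo_order].reset_index(drop=True))

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PedigreeTable":
        return cls(pd.read_csv(path))
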