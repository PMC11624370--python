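"""Readers and writers for the package's plain-text and HDF5 artifacts.

Formats:

* pedigree: CSV with columns animal,sire,dam,birth_year,sex,genotyped
  (0 = unknown parent) -- see :class:`mefeval.pedigree.PedigreeTable`;
* genotypes: animal-major text matrix (``animal g1 g2 ...`` with 0/1/2
  coding) or HDF5 (datasets ``animals``, ``genotypes``, ``allele_freqs``);
* phenotype records: CSV with the documented header (animal, herd,
  test_day, htd, dim, age_calving, year_season, lactation, ch4, my, fy, py);
* spectra: CSV (animal, date, lab, pin columns) or HDF5;
* relationship matrices: coordinate-format text via
  :meth:`mefeval.relationship.SparseSymmetric.to_coordinate_text`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RECORD_COLUMNS = [
    "animal", "herd", "test_day", "htd", "dim", "age_calving",
    "year_season", "lactation", "ch4", "my", "fy", "py",
]


def write_genotypes_text(path, animals: np.ndarray, genotypes: np.ndarray) -> None:
    with open(path, "w") as fh:
        for a, row in zip(animals, genotypes):
            fh.write(str(a) + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_genotypes_text(path) -> tuple[np.ndarray, np.ndarray]:
    animals, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            animals.append(int(parts[0]))
            rows.append([int(v) for v in parts[1:]])
    return np.array(animals), np.array(rows, dtype=np.int8)


def write_genotypes_h5(path, animals, genotypes, allele_freqs=None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("animals", data=np.asarray(animals))
        fh.create_dataset("genotypes", data=np.asarray(genotypes, dtype=np.int8))
        if allele_freqs is not None:
            fh.create_dataset("allele_freqs", data=np.asarray(allele_freqs))


def read_genotypes_h5(path):
    import h5py

    with h5py.File(path, "r") as fh:
        animals = fh["animals"][...]
        genotypes = fh["genotypes"][...]
        freqs = fh["allele_freqs"][...] if "allele_freqs" in fh else None
    return animals, genotypes, freqs


def read_plink_raw(path) -> tuple[np.ndarray, np.ndarray]:
    """PLINK ``--recode A`` additive coding: IID and SNP columns (NA -> -1)."""
    df = pd.read_csv(path, sep=r"\s+")
    snp_cols = [c for c in df.columns if c not in
                ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    geno = df[snp_cols].fillna(-1).to_numpy(dtype=np.int8)
    return df["IID"].to_numpy(), geno


def write_records(path, records: pd.DataFrame) -> None:
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    records[cols].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spectra_csv(path, index: pd.DataFrame, spectra: np.ndarray) -> None:
    """``index`` columns (animal, date, ...) followed by pin_0..pin_{p-1}."""
    pins = pd.DataFrame(
        np.asarray(spectra), columns=[f"pin_{j}" for j in range(np.asarray(spectra).shape[1])]
    )
    pd.concat([index.reset_index(drop=True), pins], axis=1).to_csv(path, index=False)


def read_spectra_csv(path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path)
    pin_cols = [c for c in df.columns if c.startswith("pin_")]
    return df.drop(columns=pin_cols), df[pin_cols].to_numpy(dtype=float)


def write_spectra_h5(path, index: pd.DataFrame, spectra: np.ndarray) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("spectra", data=np.asarray(spectra, dtype=float))
        fh.create_dataset("animal", data=index["animal"].to_numpy())
        if "date" in index:
            fh.create_dataset(
                "date", data=index["date"].astype(str).to_numpy(dtype="S")
            )


def read_spectra_h5(path) -> tuple[pd.DataFrame, np.ndarray]:
    import h5py

    with h5py.File(path, "r") as fh:
        spectra = fh["spectra"][...]
        idx = {"animal": fh["animal"][...]}
        if "date" in fh:
            idx["date"] = [d.decode() for d in fh["date"][...]]
    return pd.DataFrame(idx), spectra
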