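"""Core in-memory containers shared across the pipeline.

All genomic coordinates are 1-based inclusive (GTF/GFF convention); any
0-based source is converted at the reading boundary. Animal identifiers are
opaque strings; integer indices used for matrix algebra are assigned
internally and never leak into files.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = -1


@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    Attributes
    ----------
    ids : list of str
        Animal identifiers in pedigree (topological) order.
    sire, dam : int arrays
        Index of each animal's parent within ``ids``; ``-1`` if unknown.
    genotyped : bool array
        Flag per animal; set by :meth:`set_genotyped`.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    genotyped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.genotyped is None:
            self.genotyped = np.zeros(len(self.ids), dtype=bool)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate animal id in pedigree")
        for p in (self.sire, self.dam):
            if p.shape != (n,):
                raise ValueError("parent index arrays must match id count")
            bad = (p >= np.arange(n)) & (p != UNKNOWN_PARENT)
            if bad.any():
                raise ValueError("pedigree not in topological order")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(((self.sire == UNKNOWN_PARENT) & (self.dam == UNKNOWN_PARENT)).sum())

    def index_of(self, animal_ids) -> np.ndarray:
        """Map animal id strings to pedigree row indices."""
        try:
            return np.array([self._index[str(a)] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"animal {exc.args[0]!r} absent from pedigree") from None

    def set_genotyped(self, animal_ids) -> None:
        self.genotyped = np.zeros(len(self), dtype=bool)
        self.genotyped[self.index_of(animal_ids)] = True

    @property
    def genotyped_indices(self) -> np.ndarray:
        return np.flatnonzero(self.genotyped)

    def to_dataframe(self) -> pd.DataFrame:
        def name(idx: int) -> str:
            return "0" if idx == UNKNOWN_PARENT else self.ids[idx]

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [name(s) for s in self.sire],
                "dam": [name(d) for d in self.dam],
            }
        )


#: columns required in a SNP map frame
SNP_MAP_COLUMNS = ("snp_id", "chromosome", "position_bp")


def validate_snp_map(snp_map: pd.DataFrame, max_chromosome: int = 29) -> pd.DataFrame:
    """Validate and normalize a SNP map (1-based positions, autosome codes).

    Chromosome codes outside ``1..max_chromosome`` are allowed here (QC
    removes them); non-positive positions are not.
    """
    missing = set(SNP_MAP_COLUMNS) - set(snp_map.columns)
    if missing:
        raise ValueError(f"SNP map missing columns: {sorted(missing)}")
    out = snp_map.loc[:, list(SNP_MAP_COLUMNS)].copy()
    out["chromosome"] = out["chromosome"].astype(np.int64)
    out["position_bp"] = out["position_bp"].astype(np.int64)
    if out["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in SNP map")
    if (out["position_bp"] < 1).any():
        raise ValueError("SNP positions must be 1-based positive integers")
    return out.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Animals × SNPs allele-count matrix with its SNP map.

    ``matrix`` holds counts of the reference allele in {0, 1, 2}; missing
    entries are ``NaN`` (float storage keeps the missing mask explicit).
    """

    animal_ids: list[str]
    matrix: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.snp_map = validate_snp_map(self.snp_map)
        if self.matrix.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_map)} SNPs"
            )
        obs = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.matrix)

    def allele_frequencies(self) -> np.ndarray:
        """Observed reference-allele frequency per SNP, ignoring missing."""
        return np.nanmean(self.matrix, axis=0) / 2.0

    def mean_impute(self) -> "GenotypeMatrix":
        """Replace missing entries by 2p (expected count); returns a copy."""
        filled = self.matrix.copy()
        p = self.allele_frequencies()
        idx = np.where(np.isnan(filled))
        filled[idx] = 2.0 * p[idx[1]]
        out = GenotypeMatrix.__new__(GenotypeMatrix)
        out.animal_ids = list(self.animal_ids)
        out.matrix = filled
        out.snp_map = self.snp_map.copy()
        return out

    def subset(self, animals: np.ndarray | None = None, snps: np.ndarray | None = None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index."""
        a = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        if a.dtype == bool:
            a = np.flatnonzero(a)
        s = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if s.dtype == bool:
            s = np.flatnonzero(s)
        out = GenotypeMatrix.__new__(GenotypeMatrix)
        out.animal_ids = [self.animal_ids[i] for i in a]
        out.matrix = self.matrix[np.ix_(a, s)]
        out.snp_map = self.snp_map.iloc[s].reset_index(drop=True)
        return out


# Phenotype records travel as a pandas DataFrame with these columns:
#   animal (str), trait (str), value (float), cg (str/int contemporary
#   group), parity (int), age_days (float), age_years (int)
PHENOTYPE_COLUMNS = ("animal", "trait", "value", "cg", "parity", "age_days", "age_years")


def validate_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(PHENOTYPE_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"phenotype records missing columns: {sorted(missing)}")
    out = records.copy()
    out["animal"] = out["animal"].astype(str)
    out["trait"] = out["trait"].astype(str)
    out["value"] = out["value"].astype(np.float64)
    return out


@dataclass(frozen=True)
class GeneFeature:
    """One gene: 1-based inclusive span plus biotype."""

    gene_id: str
    chromosome: int
    start: int
    end: int
    biotype: str = "protein_coding"
    name: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")


@dataclass(frozen=True)
class QtlFeature:
    """One QTL record: span, QTL name and the trait term it was mapped for."""

    qtl_id: str
    chromosome: int
    start: int
    end: int
    trait_term: str
    trait_type: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"QTL {self.qtl_id}: end < start")
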