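"""Readers and writers for the external formats the pipeline touches.

Supported inputs: pedigree CSV/TSV (animal,sire,dam; 0/empty = unknown),
genotypes as plain TSV (0/1/2/NA with a SNP-map sidecar or header) or text
PLINK .ped/.map, gene annotation GTF and QTL annotation GFF3 (Animal-QTLdb
dialect). All outputs are TSV with a header. Coordinates are 1-based
inclusive throughout.
"""
from __future__ import annotations

import graphlib
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .datatypes import (
    UNKNOWN_PARENT,
    GeneFeature,
    GenotypeMatrix,
    Pedigree,
    QtlFeature,
    validate_phenotypes,
    validate_snp_map,
)

_MISSING_PARENT = {"0", "", "na", "nan", ".", "none"}


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_pedigree(path: str | Path) -> Pedigree:
    """Read an animal/sire/dam table and return a topologically sorted Pedigree.

    Rows may appear in any order; offspring-before-parent input is reordered.
    Raises on duplicate animal ids and on cycles (an animal that is its own
    ancestor).
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    if not {"animal", "sire", "dam"}.issubset(cols):
        raise ValueError("pedigree file must have columns animal,sire,dam")
    df.columns = cols
    return pedigree_from_frame(df)


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Build a Pedigree from an animal/sire/dam frame (strings; 0 = unknown)."""
    animals = df["animal"].astype(str).str.strip().tolist()
    if len(set(animals)) != len(animals):
        dup = df["animal"][df["animal"].duplicated()].iloc[0]
        raise ValueError(f"duplicate animal id {dup!r} in pedigree")

    def clean(col: pd.Series) -> list[str | None]:
        vals = col.astype(str).str.strip()
        return [None if v.lower() in _MISSING_PARENT else v for v in vals]

    sires = clean(df["sire"])
    dams = clean(df["dam"])
    known = set(animals)
    # parents referenced but never listed become implicit founders
    implicit = [p for p in dict.fromkeys([*sires, *dams]) if p is not None and p not in known]

    deps: dict[str, set[str]] = {a: set() for a in implicit}
    for a, s, d in zip(animals, sires, dams):
        parents = {p for p in (s, d) if p is not None}
        if a in parents:
            raise ValueError(f"animal {a!r} is its own parent")
        deps[a] = parents
    try:
        order = list(graphlib.TopologicalSorter(deps).static_order())
    except graphlib.CycleError as exc:
        raise ValueError(f"pedigree contains a cycle: {exc.args[1]}") from None

    index = {a: i for i, a in enumerate(order)}
    parent_of = {a: (s, d) for a, s, d in zip(animals, sires, dams)}
    sire_idx = np.full(len(order), UNKNOWN_PARENT, dtype=np.int64)
    dam_idx = np.full(len(order), UNKNOWN_PARENT, dtype=np.int64)
    for a, (s, d) in parent_of.items():
        i = index[a]
        if s is not None:
            sire_idx[i] = index[s]
        if d is not None:
            dam_idx[i] = index[d]
    return Pedigree(ids=order, sire=sire_idx, dam=dam_idx)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------- genotypes

def read_genotypes_tsv(matrix_path: str | Path, map_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a plain genotype TSV: first column animal id, remaining columns one
    SNP each (header = snp ids), codes 0/1/2 with NA for missing.

    If ``map_path`` is omitted, SNPs are placed on chromosome 1 at 1 Mb
    spacing (useful only for matrix-algebra work, not annotation).
    """
    df = pd.read_csv(matrix_path, sep="\t", dtype=str)
    animal_ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    mat = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    raw_nonmissing = body.notna() & ~body.isin(["NA", "na", ".", ""])
    bad = raw_nonmissing.to_numpy() & np.isnan(mat)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-numeric genotype code {body.iat[i, j]!r} at row {i}")
    if map_path is not None:
        snp_map = read_snp_map(map_path)
        if list(snp_map["snp_id"]) != list(body.columns):
            if len(snp_map) != body.shape[1]:
                raise ValueError("SNP count mismatch between matrix and map")
            raise ValueError("SNP ids in matrix header and map disagree")
    else:
        snp_map = pd.DataFrame(
            {
                "snp_id": list(body.columns),
                "chromosome": 1,
                "position_bp": (np.arange(body.shape[1]) + 1) * 1_000_000,
            }
        )
    return GenotypeMatrix(animal_ids=animal_ids, matrix=mat, snp_map=snp_map)


def write_genotypes_tsv(genotypes: GenotypeMatrix, matrix_path: str | Path, map_path: str | Path | None = None) -> None:
    body = pd.DataFrame(genotypes.matrix, columns=genotypes.snp_map["snp_id"])
    # keep integer codes in the text representation
    body = body.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    body.insert(0, "animal", genotypes.animal_ids)
    body.to_csv(matrix_path, sep="\t", index=False)
    if map_path is not None:
        write_snp_map(genotypes.snp_map, map_path)


def read_snp_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [c.lower() for c in df.columns]
    return validate_snp_map(df)


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    snp_map.to_csv(path, sep="\t", index=False)


def read_genotypes_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read text PLINK ``prefix.ped`` / ``prefix.map``.

    Alleles are re-coded per SNP so the count refers to the first allele
    observed in the file (A1); '0 0' denotes a missing genotype.
    """
    prefix = Path(prefix)
    map_rows = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp"],
        dtype={"chromosome": np.int64, "snp_id": str, "position_bp": np.int64},
    )
    snp_map = validate_snp_map(map_rows[["snp_id", "chromosome", "position_bp"]])
    n_snps = len(snp_map)

    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    a1: list[str | None] = [None] * n_snps
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_snps}"
                )
            animal_ids.append(parts[1])
            geno = np.full(n_snps, np.nan)
            alleles = parts[6:]
            for j in range(n_snps):
                x, y = alleles[2 * j], alleles[2 * j + 1]
                if x == "0" or y == "0":
                    continue
                if a1[j] is None:
                    a1[j] = x
                geno[j] = (x == a1[j]) + (y == a1[j])
            rows.append(geno)
    return GenotypeMatrix(animal_ids=animal_ids, matrix=np.vstack(rows), snp_map=snp_map)


def read_genotypes(path_or_prefix: str | Path, map_path: str | Path | None = None) -> GenotypeMatrix:
    """Dispatch on input style: PLINK prefix (``.ped`` exists) or plain TSV."""
    p = Path(path_or_prefix)
    if p.with_suffix(".ped").exists() and p.suffix != ".tsv":
        return read_genotypes_plink(p)
    return read_genotypes_tsv(p, map_path)


# ---------------------------------------------------------------- phenotypes

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep=_sniff_sep(path)))


def write_phenotypes(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- annotation

def _feature_db(path: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )


def _first_attr(feature, *keys: str, default: str = "") -> str:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return default


def read_gtf(path: str | Path) -> list[GeneFeature]:
    """Gene-level features from a GTF; duplicated gene ids are merged to the
    union of their spans (first biotype wins)."""
    db = _feature_db(path)
    genes: dict[str, GeneFeature] = {}
    for feat in db.features_of_type("gene"):
        gene_id = _first_attr(feat, "gene_id", default=feat.id)
        if feat.end < feat.start:
            raise ValueError(f"gene {gene_id}: end < start")
        chrom = int(str(feat.seqid).removeprefix("chr"))
        biotype = _first_attr(feat, "gene_biotype", "biotype", default="protein_coding")
        name = _first_attr(feat, "gene_name", default=gene_id)
        if gene_id in genes:
            prev = genes[gene_id]
            if prev.chromosome != chrom:
                raise ValueError(f"gene {gene_id} appears on two chromosomes")
            genes[gene_id] = GeneFeature(
                gene_id,
                chrom,
                min(prev.start, feat.start),
                max(prev.end, feat.end),
                prev.biotype,
                prev.name,
            )
        else:
            genes[gene_id] = GeneFeature(gene_id, chrom, feat.start, feat.end, biotype, name)
    return list(genes.values())


def read_qtl_gff(path: str | Path) -> list[QtlFeature]:
    """QTL records from an Animal-QTLdb-style GFF3 (one record per line, with
    the mapped trait in the ``trait``/``Name`` attribute and its category in
    ``trait_type``)."""
    db = _feature_db(path)
    out: list[QtlFeature] = []
    for feat in db.all_features():
        qtl_id = _first_attr(feat, "QTL_ID", "ID", default=feat.id)
        trait = _first_attr(feat, "trait", "Name")
        if feat.end < feat.start:
            raise ValueError(f"QTL {qtl_id}: end < start")
        out.append(
            QtlFeature(
                qtl_id=qtl_id,
                chromosome=int(str(feat.seqid).removeprefix("chr").removeprefix("Chr.")),
                start=feat.start,
                end=feat.end,
                trait_term=trait,
                trait_type=_first_attr(feat, "trait_type"),
            )
        )
    return out


# ---------------------------------------------------------------- results

def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Per-SNP results TSV; validates the significance/threshold contract."""
    required = {"snp_id", "chromosome", "position_bp", "p_value"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    p = results["p_value"].to_numpy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p_value must lie in (0, 1]")
    if {"significant", "threshold"}.issubset(results.columns):
        sig = results["significant"].astype(bool).to_numpy()
        if np.any(sig & (p > results["threshold"].to_numpy())):
            raise ValueError("significant flag inconsistent with threshold")
    results.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
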