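"""Pedigree and genomic relationship matrices for single-step evaluation.

Builds the numerator relationship matrix A (tabular method), its sparse
inverse by Henderson's rules with inbreeding, the VanRaden-I genomic
relationship G = ZZ'/2Σp(1−p), a G↔A22 stabilising blend, and the
single-step inverse

    H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]

with the correction block scattered onto the genotyped animals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .datatypes import UNKNOWN_PARENT, GenotypeMatrix, Pedigree


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    For animal i with parents s, d (processed in topological order):
    a_ij = (a_sj + a_dj)/2 for j < i, and a_ii = 1 + a_sd/2. Unknown parents
    contribute zero relationship.
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN_PARENT:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN_PARENT:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s, d] if (s != UNKNOWN_PARENT and d != UNKNOWN_PARENT) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return A


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """F_i = a_ii − 1, from the tabular A diagonal."""
    return np.diag(build_A(pedigree)) - 1.0


def build_A_inverse(pedigree: Pedigree, inbreeding: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules, accounting for inbreeding.

    The Mendelian-sampling variance of animal i is
    d_i = 0.5 − 0.25(F_s + F_d), 0.75 − 0.25 F_p, or 1 for two, one or no
    known parents; each animal contributes α = 1/d_i to the {i, s, d} block.
    """
    n = len(pedigree)
    if inbreeding is None:
        inbreeding = inbreeding_coefficients(pedigree)
    F = np.asarray(inbreeding, dtype=np.float64)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
        parents = [p for p in (s, d) if p != UNKNOWN_PARENT]
        if len(parents) == 2:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif len(parents) == 1:
            di = 0.75 - 0.25 * F[parents[0]]
        else:
            di = 1.0
        alpha = 1.0 / di
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-alpha / 2.0, -alpha / 2.0]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(alpha / 4.0)
    return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))


@dataclass
class Gmatrix:
    """VanRaden-I genomic relationship over the genotyped animals.

    Carries the centred covariate matrix Z, the reference-allele frequencies
    used for centring, the scale 2Σp_i(1−p_i) and the blend weight applied.
    """

    values: np.ndarray
    animal_ids: list[str]
    frequencies: np.ndarray
    scale: float
    blend_weight: float = 1.0
    Z: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def centered_Z(genotypes: GenotypeMatrix, frequencies: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Centre allele counts by twice the allele frequency; returns (Z, p)."""
    if np.isnan(genotypes.matrix).any():
        raise ValueError("missing genotypes present; impute before G construction")
    p = genotypes.allele_frequencies() if frequencies is None else np.asarray(frequencies, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = genotypes.snp_map["snp_id"].iloc[int(np.argmax((p <= 0) | (p >= 1)))]
        raise ValueError(f"monomorphic SNP {bad!r} (p=0 or 1); run QC first")
    return genotypes.matrix - 2.0 * p, p


def build_G(genotypes: GenotypeMatrix, frequencies: np.ndarray | None = None) -> Gmatrix:
    """G = ZZ'/2Σp_i(1−p_i) with Z the 2p-centred allele counts.

    Frequencies default to those observed in the genotyped set.
    """
    Z, p = centered_Z(genotypes, frequencies)
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / scale
    return Gmatrix(values=G, animal_ids=list(genotypes.animal_ids), frequencies=p, scale=scale, Z=Z)


def blend_G(G: Gmatrix, A22: np.ndarray, weight: float = 0.95) -> Gmatrix:
    """Numerical stabilisation: weight·G + (1−weight)·A22, checked PD."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("blend weight must be in [0, 1]")
    if A22.shape != G.values.shape:
        raise ValueError("A22 dimension does not match G")
    blended = weight * G.values + (1.0 - weight) * A22
    eigmin = float(scipy.linalg.eigvalsh(blended, subset_by_index=(0, 0))[0])
    if eigmin <= 0.0:
        raise ValueError(f"blended G not positive definite (min eigenvalue {eigmin:.3e})")
    return Gmatrix(
        values=blended,
        animal_ids=list(G.animal_ids),
        frequencies=G.frequencies,
        scale=G.scale,
        blend_weight=weight,
        Z=G.Z,
    )


@dataclass
class Hinverse:
    """H⁻¹ over all pedigree animals (sparse) plus its genotyped index set."""

    matrix: sp.csr_matrix
    genotyped_indices: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22: np.ndarray,
    G_blended: Gmatrix | np.ndarray,
    genotyped_indices: np.ndarray,
) -> Hinverse:
    """Assemble H⁻¹ = A⁻¹ + scatter(G⁻¹ − A22⁻¹) on the genotyped block."""
    idx = np.asarray(genotyped_indices, dtype=np.int64)
    Gv = G_blended.values if isinstance(G_blended, Gmatrix) else np.asarray(G_blended)
    n = A_inv.shape[0]
    if idx.size == 0:
        return Hinverse(matrix=sp.csr_matrix(A_inv), genotyped_indices=idx)
    if Gv.shape != (idx.size, idx.size) or A22.shape != (idx.size, idx.size):
        raise ValueError("G/A22 dimension must equal the number of genotyped animals")
    delta = _pd_inverse(Gv, "G") - _pd_inverse(A22, "A22")
    correction = sp.coo_matrix(
        (delta.ravel(), (np.repeat(idx, idx.size), np.tile(idx, idx.size))), shape=(n, n)
    )
    return Hinverse(matrix=sp.csr_matrix(A_inv + correction), genotyped_indices=idx)


def _pd_inverse(M: np.ndarray, label: str) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(M)
    except scipy.linalg.LinAlgError:
        raise ValueError(f"{label} is singular or not positive definite") from None
    inv = scipy.linalg.cho_solve((c, low), np.eye(M.shape[0]))
    return (inv + inv.T) / 2.0


def write_sparse_matrix(matrix: sp.spmatrix, ids: list[str], path: str, id_path: str) -> None:
    """Persist a symmetric sparse matrix as coordinate text (i, j, value ≥ j
    lower triangle, 1-based) with an id-map sidecar."""
    coo = sp.coo_matrix(sp.tril(matrix))
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1}\t{j + 1}\t{v:.12g}\n")
    with open(id_path, "w") as fh:
        fh.write("index\tanimal\n")
        for k, a in enumerate(ids):
            fh.write(f"{k + 1}\t{a}\n")


def read_sparse_matrix(path: str, id_path: str) -> tuple[sp.csr_matrix, list[str]]:
    import pandas as pd

    tab = pd.read_csv(path, sep="\t")
    ids = pd.read_csv(id_path, sep="\t")["animal"].astype(str).tolist()
    n = len(ids)
    i = tab["i"].to_numpy() - 1
    j = tab["j"].to_numpy() - 1
    v = tab["value"].to_numpy()
    low = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsr()
    upper = sp.triu(low.T, k=1)
    return sp.csr_matrix(low + upper), ids
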