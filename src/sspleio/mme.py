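"""Single-trait repeatability-model mixed-model equations.

Model:  y = Xb + Za + W pe + e, with Var(a) = H σ²a, Var(pe) = I σ²pe,
Var(e) = I σ²e. Variance components are fixed inputs (no REML). Henderson's
MME are assembled with λa = σ²e/σ²a on the animal block (premultiplied by
H⁻¹) and λpe = σ²e/σ²pe on the permanent-environment block, and solved by a
direct factorization at desk scale. Fixed effects: contemporary group and
parity as class effects (first level of each constrained to zero) plus an
age-in-days linear covariate nested within age-in-years class, and an
intercept.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .datatypes import Pedigree, validate_phenotypes
from .relmat import Hinverse


@dataclass
class ModelSpec:
    trait: str
    var_additive: float
    var_pe: float
    var_residual: float

    def __post_init__(self) -> None:
        if min(self.var_additive, self.var_pe, self.var_residual) <= 0:
            raise ValueError("variance components must be > 0")

    @property
    def lambda_a(self) -> float:
        return self.var_residual / self.var_additive

    @property
    def lambda_pe(self) -> float:
        return self.var_residual / self.var_pe


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix              # records × pedigree animals
    W: sp.csr_matrix              # records × animals-with-records
    fixed_names: list[str]
    record_animals: list[str]     # animal id per W column
    record_animal_rows: np.ndarray  # per-record pedigree index


def build_design(records, model_spec: ModelSpec, pedigree: Pedigree) -> DesignMatrices:
    """Incidence matrices for one trait's records.

    X holds an intercept, CG and parity one-hot columns with the first level
    dropped, and one age-in-days slope per age-in-years class. Z maps each
    record to its pedigree animal; W maps records to the animals that have
    records (permanent-environment equations exist only for those).
    """
    rec = validate_phenotypes(records)
    rec = rec[rec["trait"] == model_spec.trait].reset_index(drop=True)
    if rec.empty:
        raise ValueError(f"no records for trait {model_spec.trait!r}")
    n = len(rec)

    y = rec["value"].to_numpy(dtype=np.float64)

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for factor in ("cg", "parity"):
        levels = sorted(rec[factor].astype(str).unique())
        for lev in levels[1:]:
            cols.append((rec[factor].astype(str) == lev).to_numpy(dtype=np.float64))
            names.append(f"{factor}={lev}")
    year_classes = sorted(rec["age_years"].astype(int).unique())
    age_centered = rec["age_days"].to_numpy(dtype=np.float64)
    age_centered = age_centered - age_centered.mean()
    for yc in year_classes:
        mask = (rec["age_years"].astype(int) == yc).to_numpy(dtype=np.float64)
        cols.append(mask * age_centered)
        names.append(f"age_slope@year={yc}")
    X = np.column_stack(cols)

    animal_rows = pedigree.index_of(rec["animal"])
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), animal_rows)), shape=(n, len(pedigree))
    )
    rec_animals = sorted(rec["animal"].unique(), key=lambda a: pedigree.index_of([a])[0])
    w_index = {a: j for j, a in enumerate(rec_animals)}
    w_cols = np.array([w_index[a] for a in rec["animal"]])
    W = sp.csr_matrix((np.ones(n), (np.arange(n), w_cols)), shape=(n, len(rec_animals)))

    return DesignMatrices(
        y=y, X=X, Z=Z, W=W, fixed_names=names,
        record_animals=rec_animals, record_animal_rows=animal_rows,
    )


@dataclass
class ModelSolution:
    b: np.ndarray
    fixed_names: list[str]
    a: np.ndarray                 # GEBV per pedigree animal
    pe: np.ndarray
    record_animals: list[str]
    residual_norm: float
    design: DesignMatrices = field(repr=False)
    spec: ModelSpec = field(repr=False)
    lhs_inverse: np.ndarray | None = field(default=None, repr=False)
    constrained_columns: list[int] = field(default_factory=list)

    def gebv(self, pedigree: Pedigree, animal_ids) -> np.ndarray:
        return self.a[pedigree.index_of(animal_ids)]

    def pev_a(self) -> np.ndarray:
        """Prediction-error covariance of â: C^aa · σ²e from the LHS inverse."""
        if self.lhs_inverse is None:
            raise ValueError("solve_mme(..., compute_lhs_inverse=True) required")
        p = len(self.b)
        na = self.a.size
        return self.lhs_inverse[p : p + na, p : p + na] * self.spec.var_residual


def solve_mme(
    design: DesignMatrices,
    H_inv: Hinverse | sp.spmatrix | np.ndarray,
    model_spec: ModelSpec,
    tol: float = 1e-10,
    compute_lhs_inverse: bool = False,
) -> ModelSolution:
    """Assemble and solve Henderson's MME by dense Cholesky factorization.

    Rank deficiency in X (beyond the reference-level constraints already
    applied) is handled by zeroing dependent columns — a generalized-inverse
    constraint, reported in ``constrained_columns``.
    """
    Hm = H_inv.matrix if isinstance(H_inv, Hinverse) else sp.csr_matrix(H_inv)
    X, Z, W, y = design.X, design.Z, design.W, design.y
    n_a = Hm.shape[0]
    if Z.shape[1] != n_a:
        raise ValueError("H⁻¹ dimension must equal the pedigree size")
    lam_a = model_spec.lambda_a
    lam_pe = model_spec.lambda_pe

    p = X.shape[1]
    n_pe = W.shape[1]
    dim = p + n_a + n_pe

    XtX = X.T @ X
    XtZ = (Z.T @ X).T
    XtW = (W.T @ X).T
    ZtZ = (Z.T @ Z).toarray()
    ZtW = (Z.T @ W).toarray()
    WtW = (W.T @ W).toarray()

    lhs = np.zeros((dim, dim))
    lhs[:p, :p] = XtX
    lhs[:p, p : p + n_a] = XtZ
    lhs[p : p + n_a, :p] = XtZ.T
    lhs[:p, p + n_a :] = XtW
    lhs[p + n_a :, :p] = XtW.T
    lhs[p : p + n_a, p : p + n_a] = ZtZ + lam_a * Hm.toarray()
    lhs[p : p + n_a, p + n_a :] = ZtW
    lhs[p + n_a :, p : p + n_a] = ZtW.T
    lhs[p + n_a :, p + n_a :] = WtW + lam_pe * np.eye(n_pe)

    rhs = np.concatenate([X.T @ y, Z.T @ y, W.T @ y])

    constrained: list[int] = []
    sol, lhs_inv = _solve_psd(lhs, rhs, constrained, compute_lhs_inverse)

    resid = lhs @ sol - rhs
    rel = float(np.linalg.norm(resid) / max(np.linalg.norm(rhs), 1.0))
    if rel > tol:
        warnings.warn(f"MME relative residual {rel:.2e} exceeds tol {tol:.1e}", stacklevel=2)

    return ModelSolution(
        b=sol[:p],
        fixed_names=design.fixed_names,
        a=sol[p : p + n_a],
        pe=sol[p + n_a :],
        record_animals=design.record_animals,
        residual_norm=rel,
        design=design,
        spec=model_spec,
        lhs_inverse=lhs_inv,
        constrained_columns=constrained,
    )


def _solve_psd(lhs, rhs, constrained: list[int], want_inverse: bool):
    try:
        c = scipy.linalg.cho_factor(lhs, check_finite=False)
        sol = scipy.linalg.cho_solve(c, rhs, check_finite=False)
        inv = scipy.linalg.cho_solve(c, np.eye(lhs.shape[0]), check_finite=False) if want_inverse else None
        return sol, inv
    except scipy.linalg.LinAlgError:
        # rank-deficient: drop (zero) dependent equations via pinv
        inv = np.linalg.pinv(lhs, hermitian=True)
        sol = inv @ rhs
        diag_null = np.flatnonzero(np.abs(np.diag(lhs)) < 1e-12)
        constrained.extend(int(i) for i in diag_null)
        return sol, (inv if want_inverse else None)


def adjust_phenotypes(design: DesignMatrices, solution: ModelSolution) -> "np.ndarray":
    """Per-animal mean of fixed-effect-adjusted records: mean_i(y − Xb̂).

    Returns an array aligned with ``solution.record_animals``.
    """
    ystar = design.y - design.X @ solution.b
    sums = design.W.T @ ystar
    counts = np.asarray(design.W.sum(axis=0)).ravel()
    return sums / counts


def adjusted_means_frame(records, pedigree: Pedigree, specs: list[ModelSpec], H_inv, compute_lhs_inverse=False):
    """Fit each trait's repeatability model and return a wide per-animal
    table of adjusted means (NaN where the animal lacks records), plus the
    per-trait solutions."""
    import pandas as pd

    solutions: dict[str, ModelSolution] = {}
    frames = []
    for spec in specs:
        design = build_design(records, spec, pedigree)
        solution = solve_mme(design, H_inv, spec, compute_lhs_inverse=compute_lhs_inverse)
        solutions[spec.trait] = solution
        adj = adjust_phenotypes(design, solution)
        frames.append(pd.Series(adj, index=solution.record_animals, name=spec.trait))
    table = pd.concat(frames, axis=1)
    table.index.name = "animal"
    return table, solutions
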