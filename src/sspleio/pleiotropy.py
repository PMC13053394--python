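"""Cholesky decorrelation of correlated traits and the multi-trait χ² scan.

Procedure (for k traits, here body condition score → mature weight →
mature height):

1. take each animal's average fixed-effect-adjusted phenotype per trait;
2. z-score each trait on its complete-case mean/SD and estimate COV, the
   k×k covariance (= correlation) matrix of the z-scores on complete cases;
3. transform c_n = L⁻¹ g_n with L the lower Cholesky factor of COV — the
   j-th Cholesky-transformed trait (CT) is trait j corrected for traits
   1..j−1, and CT_1 equals the first z-scored trait; an animal gets CT_j
   whenever it observes traits 1..j;
4. run a mean-only animal-model GWAS per CT and keep each SNP's signed
   t-value (effect/SE);
5. per SNP, the pleiotropy statistic is χ² = t' V⁻¹ t with V the k×k
   correlation matrix of signed t-values across all SNPs, referred to a χ²
   distribution with k degrees of freedom, and Bonferroni-corrected with the
   same chromosome-wise segment thresholds as the single-trait scan.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .datatypes import GenotypeMatrix, Pedigree
from .relmat import Gmatrix, Hinverse, _pd_inverse
from .ssgwas import (
    SegmentThresholds,
    backsolve_snp_effects,
    call_significant,
    gebv_estimator_covariance,
    snp_effect_se,
)


@dataclass
class CholeskyTraits:
    """Per-animal Cholesky-transformed trait values plus the transform."""

    values: pd.DataFrame          # animals × CT columns (NaN where undefined)
    order: list[str]
    L: np.ndarray                 # lower Cholesky factor of COV
    cov: np.ndarray               # covariance of z-scored traits, complete cases
    z_means: np.ndarray
    z_sds: np.ndarray

    @property
    def k(self) -> int:
        return len(self.order)


def zscore_and_cholesky(adjusted_means: pd.DataFrame, order: list[str] | None = None) -> CholeskyTraits:
    """Z-score, estimate COV on complete cases, and apply c = L⁻¹ g.

    ``adjusted_means`` is a per-animal wide table (one column per trait,
    NaN = trait unobserved). CT_j is produced for every animal observing
    traits 1..j of the transform order; later-trait availability is
    irrelevant to earlier CTs.
    """
    order = list(adjusted_means.columns) if order is None else list(order)
    g = adjusted_means.loc[:, order]
    complete = g.dropna()
    if len(complete) < 2:
        raise ValueError("need at least 2 complete-case animals")
    mu = complete.mean().to_numpy()
    sd = complete.std(ddof=1).to_numpy()
    if np.any(sd == 0):
        raise ValueError("a trait has zero variance on complete cases")
    z = (g - mu) / sd
    # covariance of the z-scores on complete cases = the complete-case
    # correlation matrix; its diagonal is exactly 1, so the Cholesky factor
    # has L[0,0] = 1 and CT_1 reproduces the first z-scored trait exactly
    cov = np.corrcoef(complete.to_numpy(), rowvar=False)
    np.fill_diagonal(cov, 1.0)
    try:
        L = scipy.linalg.cholesky(cov, lower=True)
    except scipy.linalg.LinAlgError:
        raise ValueError("trait covariance is not positive definite (duplicated trait?)") from None

    k = len(order)
    zv = z.to_numpy()
    ct = np.full_like(zv, np.nan)
    # forward substitution row-block-wise over missingness prefixes: CT_j
    # needs traits 1..j, so solve the leading j×j triangle
    prefix_len = np.zeros(len(z), dtype=int)
    obs = ~np.isnan(zv)
    for j in range(k):
        prefix_len[(prefix_len == j) & obs[:, j]] = j + 1
    for m in range(1, k + 1):
        rows = np.flatnonzero(prefix_len == m) if m < k else np.flatnonzero(prefix_len >= m)
        if rows.size == 0:
            continue
        sub = scipy.linalg.solve_triangular(L[:m, :m], zv[np.ix_(rows, range(m))].T, lower=True)
        ct[np.ix_(rows, range(m))] = sub.T
    values = pd.DataFrame(ct, index=adjusted_means.index, columns=[f"{t}_CT" for t in order])
    return CholeskyTraits(values=values, order=order, L=L, cov=cov, z_means=mu, z_sds=sd)


def effective_single_record_h2(var_additive: float, var_pe: float, var_residual: float, mean_records: float = 1.0) -> float:
    """Heritability of an animal's averaged adjusted phenotype.

    Averaging m records shrinks the residual to σ²e/m while the permanent
    environment stays whole: h²_eff = σ²a / (σ²a + σ²pe + σ²e/m̄). This is
    the default variance ratio handed to the per-CT GWAS.
    """
    if mean_records <= 0:
        raise ValueError("mean_records must be > 0")
    return var_additive / (var_additive + var_pe + var_residual / mean_records)


@dataclass
class CtGwasResult:
    """Per-CT back-solved SNP effects, SEs and signed t-values."""

    snp_map: pd.DataFrame
    effects: pd.DataFrame         # SNPs × CT columns
    se: pd.DataFrame
    t_values: pd.DataFrame


def _fit_mean_animal_model(
    values: pd.Series,
    relationship_inv: np.ndarray,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve y = 1μ + a + e with Var(a) ∝ K; returns (â, LHS inverse).

    ``relationship_inv`` is K⁻¹ over the animals carrying values (already
    subset and inverted by the caller); λ = σ²e/σ²a on the z-scored scale.
    """
    y = values.to_numpy(dtype=float)
    n = y.size
    dim = n + 1
    lhs = np.zeros((dim, dim))
    lhs[0, 0] = n
    lhs[0, 1:] = 1.0
    lhs[1:, 0] = 1.0
    lhs[1:, 1:] = np.eye(n) + lam * relationship_inv
    rhs = np.concatenate([[y.sum()], y])
    c = scipy.linalg.cho_factor(lhs, check_finite=False)
    inv = scipy.linalg.cho_solve(c, np.eye(dim), check_finite=False)
    sol = inv @ rhs
    return sol[1:], inv


def gwas_per_ct(
    cholesky_traits: CholeskyTraits,
    genotypes: GenotypeMatrix,
    G: Gmatrix,
    heritability: dict[str, float] | float = 0.4,
    H_inv: Hinverse | None = None,
    pedigree: Pedigree | None = None,
    var_residual_scale: float = 1.0,
) -> CtGwasResult:
    """Mean-only animal-model GWAS of each CT; emits signed t-values.

    By default each CT is analysed with a genotyped-only GBLUP on the
    (blended) G of the animals that carry the CT. Passing ``H_inv`` and
    ``pedigree`` switches to the single-step model over the whole pedigree.
    ``heritability`` is the assumed single-record h² per CT (the share of
    the z-scored CT variance that is additive); a scalar applies to all CTs.
    """
    Z_full = G.Z
    if Z_full is None:
        raise ValueError("G must carry its centred covariates Z (build_G output)")
    gid = {a: i for i, a in enumerate(G.animal_ids)}
    eff, ses, ts = {}, {}, {}
    for ct_col, trait in zip(cholesky_traits.values.columns, cholesky_traits.order):
        h2 = heritability.get(trait, 0.4) if isinstance(heritability, dict) else float(heritability)
        if not 0.0 < h2 < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        lam = (1.0 - h2) / h2 * var_residual_scale
        vals = cholesky_traits.values[ct_col].dropna()
        if H_inv is not None and pedigree is not None:
            a_hat, var_a = _single_step_ct(vals, pedigree, H_inv, G, h2)
            rows = [gid[a] for a in G.animal_ids]
        else:
            keep = [a for a in vals.index.astype(str) if a in gid]
            vals = vals.loc[keep]
            rows = [gid[a] for a in keep]
            Ksub = G.values[np.ix_(rows, rows)]
            K_inv = _pd_inverse(Ksub, "G subset")
            a_hat, lhs_inv = _fit_mean_animal_model(vals, K_inv, lam)
            pev = lhs_inv[1:, 1:] * (1.0 - h2)  # σ²e on the unit-variance scale
            var_a = gebv_estimator_covariance(Ksub, pev, h2)
        Z = Z_full[rows]
        # blending-consistent regularization of (ZZ')⁻¹: use the (blended)
        # relationship actually fitted, times its VanRaden scale
        zzt = G.scale * G.values[np.ix_(rows, rows)]
        u = backsolve_snp_effects(a_hat, Z, zzt=zzt)
        sd = snp_effect_se(var_a, Z, zzt=zzt)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, u / sd, 0.0)
        eff[ct_col], ses[ct_col], ts[ct_col] = u, sd, t
    smap = genotypes.snp_map.copy()
    return CtGwasResult(
        snp_map=smap,
        effects=pd.DataFrame(eff, index=smap["snp_id"]),
        se=pd.DataFrame(ses, index=smap["snp_id"]),
        t_values=pd.DataFrame(ts, index=smap["snp_id"]),
    )


def _single_step_ct(vals: pd.Series, pedigree: Pedigree, H_inv: Hinverse, G: Gmatrix, h2: float):
    """Mean + animal model over the full pedigree with H⁻¹; returns â and
    Var(â) restricted to the genotyped animals (G order)."""
    lam = (1.0 - h2) / h2
    n_a = H_inv.n
    rec_rows = pedigree.index_of(vals.index)
    n = len(vals)
    dim = 1 + n_a
    lhs = np.zeros((dim, dim))
    lhs[0, 0] = n
    incid = np.zeros(n_a)
    np.add.at(incid, rec_rows, 1.0)
    lhs[0, 1:] = incid
    lhs[1:, 0] = incid
    ZtZ = np.zeros((n_a, n_a))
    ZtZ[rec_rows, rec_rows] = 1.0
    lhs[1:, 1:] = ZtZ + lam * H_inv.toarray()
    y = vals.to_numpy(dtype=float)
    rhs = np.zeros(dim)
    rhs[0] = y.sum()
    np.add.at(rhs, 1 + rec_rows, y)
    c = scipy.linalg.cho_factor(lhs, check_finite=False)
    inv = scipy.linalg.cho_solve(c, np.eye(dim), check_finite=False)
    sol = inv @ rhs
    gidx = pedigree.index_of(G.animal_ids)
    a_hat = sol[1 + gidx]
    pev = inv[np.ix_(1 + gidx, 1 + gidx)] * (1.0 - h2)
    var_a = gebv_estimator_covariance(G.values, pev, h2)
    return a_hat, var_a


def snp_t_correlation(t_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pearson correlation of signed t-values across SNPs between CTs."""
    T = t_matrix.to_numpy() if isinstance(t_matrix, pd.DataFrame) else np.asarray(t_matrix)
    if T.ndim == 1:
        T = T[:, None]
    if T.shape[0] < 2:
        raise ValueError("need at least 2 SNPs to estimate V")
    if not np.isfinite(T).all():
        raise ValueError("non-finite t-values")
    sd = T.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance t-value column")
    if T.shape[1] == 1:
        return np.array([[1.0]])
    return np.corrcoef(T, rowvar=False)


def multitrait_chisq(t_values: np.ndarray, V: np.ndarray, cond_warn: float = 1e8) -> tuple[np.ndarray, np.ndarray]:
    """χ² = t'V⁻¹t per SNP and its upper-tail p on k df.

    V is inverted with a pseudo-inverse; a condition number above
    ``cond_warn`` triggers a warning (near-duplicated CT columns).
    """
    T = np.atleast_2d(np.asarray(t_values, dtype=float))
    k = V.shape[0]
    if T.shape[1] != k:
        raise ValueError("t-value width must match V")
    cond = np.linalg.cond(V)
    if cond > cond_warn:
        warnings.warn(f"V condition number {cond:.2e}; χ² unstable", stacklevel=2)
    V_inv = np.linalg.pinv(V, hermitian=True)
    chi2 = np.einsum("ij,jk,ik->i", T, V_inv, T)
    chi2 = np.clip(chi2, 0.0, None)
    p = stats.chi2.sf(chi2, df=k)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return chi2, p


@dataclass
class MultiTraitResult:
    table: pd.DataFrame           # snp_id, chromosome, position_bp, t_*, chisq, p_value [, threshold, significant]
    V: np.ndarray
    order: list[str] = field(default_factory=list)


def run_multitrait_scan(
    ct_gwas: CtGwasResult,
    thresholds: SegmentThresholds | None = None,
) -> MultiTraitResult:
    """Assemble the per-SNP multi-trait χ² table from per-CT signed t-values."""
    V = snp_t_correlation(ct_gwas.t_values)
    chi2, p = multitrait_chisq(ct_gwas.t_values.to_numpy(), V)
    out = ct_gwas.snp_map.copy()
    for col in ct_gwas.t_values.columns:
        out[f"t_{col}"] = ct_gwas.t_values[col].to_numpy()
    out["chisq"] = chi2
    out["p_value"] = p
    if thresholds is not None:
        flags, thr = call_significant(p, out["chromosome"].to_numpy(), thresholds)
        out["threshold"] = thr
        out["significant"] = flags
    return MultiTraitResult(table=out, V=V, order=list(ct_gwas.t_values.columns))


def call_pleiotropic(result: MultiTraitResult, thresholds: SegmentThresholds) -> MultiTraitResult:
    """Chromosome-wise Bonferroni call on the multi-trait p-values."""
    out = result.table.copy()
    flags, thr = call_significant(
        out["p_value"].to_numpy(), out["chromosome"].to_numpy(), thresholds
    )
    out["threshold"] = thr
    out["significant"] = flags
    return MultiTraitResult(table=out, V=result.V, order=result.order)
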