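"""SNP effects back-solved from GEBVs, with tests and chromosome-wise
multiple-testing thresholds.

Given the GEBVs â of the genotyped animals and the centred genotype
covariates Z used to build G, SNP allele-substitution effects under the
equal-variance (infinitesimal) assumption are

    û = Z' (Z Z')⁻¹ â

with sampling variance propagated linearly, Var(û) = K Var(â) K' for
K = Z'(ZZ')⁻¹; two-sided normal p-values p = 2(1 − Φ(|û/SD(û)|)); per-SNP
variance explained 2p(1−p)û²/σ²a; and a Bonferroni correction at α = 0.05
over the effective number of independent chromosome segments
Me = 2·Ne·L / ln(4·Ne·L) (L in Morgans), giving chromosome-wise thresholds
α_c = 0.05 / Me_c.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats


def _zzt_solve(Z: np.ndarray, B: np.ndarray, ridge: float | None = None, zzt: np.ndarray | None = None) -> np.ndarray:
    """Solve (ZZ') x = B columns, adding a trace-scaled ridge if near-singular.

    With observed-frequency centring ZZ' is singular by construction (its
    rows sum to ~0), so pipeline callers pass ``zzt`` — the blended
    relationship times its scale — as the blending-consistent regularization.
    """
    ZZt = Z @ Z.T if zzt is None else np.asarray(zzt)
    n = ZZt.shape[0]
    if ridge is None:
        ridge = 0.0
    attempt = ZZt + ridge * np.eye(n)
    try:
        c = scipy.linalg.cho_factor(attempt, check_finite=False)
    except scipy.linalg.LinAlgError:
        auto = 1e-8 * np.trace(ZZt) / n
        warnings.warn(
            f"ZZ' near-singular; adding trace-scaled ridge {auto:.3e}", stacklevel=3
        )
        c = scipy.linalg.cho_factor(ZZt + auto * np.eye(n), check_finite=False)
    return scipy.linalg.cho_solve(c, B, check_finite=False)


def backsolve_snp_effects(gebv: np.ndarray, Z: np.ndarray, ridge: float | None = None, zzt: np.ndarray | None = None) -> np.ndarray:
    """û = Z'(ZZ')⁻¹â; the reconstruction Zû equals â up to conditioning."""
    gebv = np.asarray(gebv, dtype=np.float64)
    if gebv.shape[0] != Z.shape[0]:
        raise ValueError("GEBV length must equal the number of genotyped animals")
    return Z.T @ _zzt_solve(Z, gebv, ridge, zzt)


def backsolve_operator(Z: np.ndarray, ridge: float | None = None, zzt: np.ndarray | None = None) -> np.ndarray:
    """K = Z'(ZZ')⁻¹ (SNPs × animals), the linear map from â to û."""
    return Z.T @ _zzt_solve(Z, np.eye(Z.shape[0]), ridge, zzt)


def snp_effect_se(var_gebv: np.ndarray, Z: np.ndarray, ridge: float | None = None, zzt: np.ndarray | None = None) -> np.ndarray:
    """SD(û_i) from Var(û) = K Var(â) K' (diagonal only).

    ``var_gebv`` is the covariance matrix of the GEBV estimates over the
    genotyped animals; for BLUP this is Var(â) = G σ²a − PEV(â).
    """
    K = backsolve_operator(Z, ridge, zzt)
    var_u = np.einsum("ij,jk,ik->i", K, var_gebv, K)
    return np.sqrt(np.clip(var_u, 0.0, None))


def gebv_estimator_covariance(G_values: np.ndarray, pev: np.ndarray, var_additive: float) -> np.ndarray:
    """Var(â) = G σ²a − PEV(â), symmetrized and eigenvalue-floored at zero.

    For BLUP with known variances Cov(â, a) = Var(â), hence
    Var(â) = Var(a) − PEV.
    """
    V = G_values * var_additive - pev
    V = (V + V.T) / 2.0
    w, Q = scipy.linalg.eigh(V)
    if w[0] < 0:
        V = (Q * np.clip(w, 0.0, None)) @ Q.T
    return V


def snp_pvalues(effects: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal p-values, p = 2(1 − Φ(|û/SD|)).

    SNPs with SD = 0 get NaN with a warning (degenerate, typically Var(â)=0).
    """
    effects = np.asarray(effects, dtype=float)
    sd = np.asarray(sd, dtype=float)
    p = np.full(effects.shape, np.nan)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} SNP(s) with SD=0; p-value set missing", stacklevel=2)
    t = np.abs(effects[ok] / sd[ok])
    p[ok] = 2.0 * stats.norm.sf(t)
    # numerically, p is in (0, 1]; clip the underflow-to-0 tail to the
    # smallest positive float so downstream log-scale plots stay finite
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    return p


def variance_explained(effects: np.ndarray, frequencies: np.ndarray, var_additive: float) -> np.ndarray:
    """Per-SNP fraction of additive genetic variance: 2p(1−p)û²/σ²a.

    Additive over disjoint SNP sets by construction (ignores LD covariance).
    """
    if var_additive <= 0:
        raise ValueError("var_additive must be > 0")
    p = np.asarray(frequencies, dtype=float)
    u = np.asarray(effects, dtype=float)
    return 2.0 * p * (1.0 - p) * u**2 / var_additive


@dataclass
class SegmentThresholds:
    """Per-chromosome effective segment counts and Bonferroni thresholds."""

    table: pd.DataFrame  # chromosome, length_morgans, me, alpha
    ne: int
    alpha: float = 0.05

    def alpha_for(self, chromosome: int) -> float:
        row = self.table.loc[self.table["chromosome"] == chromosome, "alpha_c"]
        if row.empty:
            raise KeyError(f"no threshold for chromosome {chromosome}")
        return float(row.iloc[0])


def effective_segments(
    chromosome_lengths_morgans: dict[int, float],
    ne: int = 182,
    alpha: float = 0.05,
    use_average_length: bool = False,
) -> SegmentThresholds:
    """Me_c = 2·Ne·L_c / ln(4·Ne·L_c) and α_c = α / Me_c per chromosome.

    With ``use_average_length`` a single genome-average L replaces each
    chromosome's own length (the two readings of "average chromosome
    length"; per-chromosome is the default).
    """
    lengths = dict(chromosome_lengths_morgans)
    if any(length <= 0 for length in lengths.values()):
        raise ValueError("chromosome lengths must be > 0")
    if use_average_length:
        avg = float(np.mean(list(lengths.values())))
        lengths = {c: avg for c in lengths}
    rows = []
    for c, L in sorted(lengths.items()):
        if 4.0 * ne * L <= 1.0:
            raise ValueError(f"chromosome {c}: 4·Ne·L must exceed 1 for the segment formula")
        me = 2.0 * ne * L / np.log(4.0 * ne * L)
        rows.append((c, L, me, alpha / me))
    return SegmentThresholds(
        table=pd.DataFrame(rows, columns=["chromosome", "length_morgans", "me", "alpha_c"]),
        ne=ne,
        alpha=alpha,
    )


def call_significant(p_values: np.ndarray, chromosomes: np.ndarray, thresholds: SegmentThresholds) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome-wise Bonferroni call: significant iff p ≤ α_c (boundary
    inclusive). Returns (flags, per-SNP threshold)."""
    chromosomes = np.asarray(chromosomes)
    thr = np.array([thresholds.alpha_for(int(c)) for c in chromosomes])
    p = np.asarray(p_values, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    flags[ok] = p[ok] <= thr[ok]
    return flags, thr


def run_ssgwas(
    gebv: np.ndarray,
    Z: np.ndarray,
    snp_map: pd.DataFrame,
    frequencies: np.ndarray,
    var_additive: float,
    var_gebv: np.ndarray | None = None,
    thresholds: SegmentThresholds | None = None,
    ridge: float | None = None,
    zzt: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-SNP results table for one trait.

    When ``var_gebv`` is omitted, SEs, t and p are left NaN (effects-only
    mode). When ``thresholds`` is given the table also carries the
    chromosome threshold and significance flag. Pass ``zzt`` (blended
    relationship × its scale) to regularize the (ZZ')⁻¹ consistently with
    the G used in the evaluation.
    """
    u = backsolve_snp_effects(gebv, Z, ridge, zzt)
    out = snp_map.copy()
    out["effect"] = u
    out["var_explained"] = variance_explained(u, frequencies, var_additive)
    if var_gebv is not None:
        sd = snp_effect_se(var_gebv, Z, ridge, zzt)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["se"] = sd
            out["t_value"] = np.where(sd > 0, u / sd, np.nan)
        out["p_value"] = snp_pvalues(u, sd)
    else:
        out["se"] = np.nan
        out["t_value"] = np.nan
        out["p_value"] = np.nan
    if thresholds is not None and var_gebv is not None:
        flags, thr = call_significant(out["p_value"].to_numpy(), out["chromosome"].to_numpy(), thresholds)
        out["threshold"] = thr
        out["significant"] = flags
    return out
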