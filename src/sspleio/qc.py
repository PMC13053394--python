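"""Phenotype and genotype quality control.

Phenotype rules (applied in this order, once, non-iteratively):
  1. age window — cows younger than ``min_age_years`` or older than
     ``max_age_years`` at recording are dropped;
  2. contemporary-group size — CGs with fewer than ``cg_min`` animals are
     excluded;
  3. outliers — for traits in ``sd_traits`` (weight/height style traits),
     records more than ``sd_limit`` SDs from their CG mean are removed;
  4. variability — for traits in ``zero_var_traits`` (scored traits such as
     body condition score), CGs without variability are removed entirely.

Genotype rules (in this order): valid position → autosome → SNP call rate →
animal call rate → MAF → |observed − expected heterozygosity|, expected
being 2p(1−p). All inequalities are strict, exactly as stated for each rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, validate_phenotypes


@dataclass
class QcReport:
    """Counts before/after each named filter, in application order."""

    unit: str  # "records", "snps", "animals"
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, before: int, after: int) -> None:
        if after > before:
            raise ValueError(f"filter {name!r} increased the count")
        self.steps.append((name, before, after))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "before", "after"]).assign(
            removed=lambda d: d["before"] - d["after"], unit=self.unit
        )

    @property
    def final_count(self) -> int:
        return self.steps[-1][2] if self.steps else 0


def filter_phenotypes(
    records: pd.DataFrame,
    cg_min: int = 3,
    sd_limit: float = 3.0,
    min_age_years: float = 1.0,
    max_age_years: float = 15.0,
    sd_traits: tuple[str, ...] = ("MWT", "MHT"),
    zero_var_traits: tuple[str, ...] = ("BCS",),
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the phenotype QC chain; returns surviving records and a report.

    CG membership is counted per trait×CG cell (a group is a management
    cell within one trait). Unknown trait labels (present in the data but in
    neither trait list) raise.
    """
    rec = validate_phenotypes(records)
    known = set(sd_traits) | set(zero_var_traits)
    unknown = set(rec["trait"].unique()) - known
    if unknown:
        raise ValueError(f"unknown trait label(s): {sorted(unknown)}")

    report = QcReport(unit="records")
    n0 = len(rec)
    age_y = rec["age_days"] / 365.25
    rec = rec[(age_y >= min_age_years) & (age_y <= max_age_years)]
    report.add("age_window", n0, len(rec))

    n0 = len(rec)
    sizes = rec.groupby(["trait", "cg"])["animal"].transform("nunique")
    rec = rec[sizes >= cg_min]
    report.add("cg_min_size", n0, len(rec))

    n0 = len(rec)
    grp = rec.groupby(["trait", "cg"])["value"]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    is_sd_trait = rec["trait"].isin(sd_traits)
    outlier = is_sd_trait & (sd > 0) & ((rec["value"] - mean).abs() > sd_limit * sd)
    rec = rec[~outlier]
    report.add("cg_sd_outlier", n0, len(rec))

    n0 = len(rec)
    var = rec.groupby(["trait", "cg"])["value"].transform("var").fillna(0.0)
    no_var = rec["trait"].isin(zero_var_traits) & (var == 0.0)
    rec = rec[~no_var]
    report.add("cg_zero_variance", n0, len(rec))

    return rec.reset_index(drop=True), report


def heterozygosity_difference(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP observed vs expected (2p(1−p)) heterozygosity and an exact
    Hardy–Weinberg test p-value, emitted for inspection."""
    m = genotypes.matrix
    obs_het = np.nanmean(m == 1.0, axis=0)
    p = genotypes.allele_frequencies()
    exp_het = 2.0 * p * (1.0 - p)
    n_obs = (~np.isnan(m)).sum(axis=0)
    # chi-square HWE test (1 df) on genotype counts
    pvals = np.ones(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        col = m[:, j]
        col = col[~np.isnan(col)]
        n = col.size
        if n == 0 or p[j] in (0.0, 1.0):
            continue
        obs = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()])
        q = 1.0 - p[j]
        exp = n * np.array([q**2, 2 * p[j] * q, p[j] ** 2])
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
        pvals[j] = float(stats.chi2.sf(chi2, df=1))
    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_map["snp_id"],
            "obs_het": obs_het,
            "exp_het": exp_het,
            "het_diff": np.abs(obs_het - exp_het),
            "hwe_p": pvals,
            "n_obs": n_obs,
        }
    )


def filter_genotypes(
    genotypes: GenotypeMatrix,
    call_rate: float = 0.90,
    maf: float = 0.05,
    het_diff: float = 0.15,
    max_autosome: int = 29,
) -> tuple[GenotypeMatrix, QcReport, QcReport]:
    """Apply the genotype QC chain; returns (filtered genotypes, SNP report,
    animal report).

    Order: unknown/duplicated position → non-autosome → SNP call rate →
    animal call rate → MAF → heterozygosity difference. Frequencies for the
    MAF and heterozygosity rules are recomputed on the retained animals.
    """
    snp_rep = QcReport(unit="snps")
    ani_rep = QcReport(unit="animals")
    g = genotypes

    n0 = g.n_snps
    smap = g.snp_map
    valid_pos = smap["position_bp"].to_numpy() >= 1
    dup = smap.duplicated(subset=["chromosome", "position_bp"], keep=False).to_numpy()
    keep = valid_pos & ~dup
    g = g.subset(snps=keep)
    snp_rep.add("position_valid_unique", n0, g.n_snps)

    n0 = g.n_snps
    chrom = g.snp_map["chromosome"].to_numpy()
    g = g.subset(snps=(chrom >= 1) & (chrom <= max_autosome))
    snp_rep.add("autosome", n0, g.n_snps)

    n0 = g.n_snps
    snp_cr = 1.0 - g.missing_mask.mean(axis=0)
    g = g.subset(snps=~(snp_cr < call_rate))
    snp_rep.add("snp_call_rate", n0, g.n_snps)

    a0 = g.n_animals
    ani_cr = 1.0 - g.missing_mask.mean(axis=1)
    g = g.subset(animals=~(ani_cr < call_rate))
    ani_rep.add("animal_call_rate", a0, g.n_animals)

    n0 = g.n_snps
    p = g.allele_frequencies()
    maf_obs = np.minimum(p, 1.0 - p)
    g = g.subset(snps=~(maf_obs < maf))
    snp_rep.add("maf", n0, g.n_snps)

    n0 = g.n_snps
    het = heterozygosity_difference(g)
    g = g.subset(snps=~(het["het_diff"].to_numpy() > het_diff))
    snp_rep.add("het_difference", n0, g.n_snps)

    return g, snp_rep, ani_rep
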