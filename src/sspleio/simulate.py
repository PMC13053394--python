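"""Synthetic pedigree / genotype / phenotype generator with known truth.

The generator emulates the data structure of a breed-association evaluation:
a multi-generation random-mating pedigree with a genotyped subset, biallelic
SNPs whose linkage disequilibrium decays with physical distance, and
repeated records per cow under a repeatability model

    y = CG + parity + age-slope(year-class)·age_days + a + pe + e

for several genetically correlated traits. Trait genetics decompose into a
pedigree-driven polygenic term (exact variance by construction) plus
explicit QTL effects at known SNPs, so every downstream stage can be scored
against ground truth.

Founder haplotypes follow a mosaic-of-ancestors model: each founder
haplotype copies from a small pool of ancestral haplotypes and switches
ancestor between adjacent SNPs with probability 1 − exp(−ld_decay_rate·d)
for d bp, which yields r² decaying approximately exponentially with
distance. Descendant haplotypes are gene-dropped with Haldane (Poisson)
recombination on the Morgan scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import UNKNOWN_PARENT, GenotypeMatrix, Pedigree
from .relmat import inbreeding_coefficients

DEFAULT_TRAITS = ("BCS", "MWT", "MHT")


@dataclass
class TraitSpec:
    """Variance components of one trait (observation-scale units²)."""

    name: str
    var_additive: float = 0.4       # polygenic σ²a
    var_pe: float = 0.2             # permanent environment σ²pe
    var_residual: float = 0.4       # σ²e

    def __post_init__(self) -> None:
        if min(self.var_additive, self.var_pe, self.var_residual) <= 0:
            raise ValueError(f"trait {self.name}: variances must be > 0")

    @property
    def repeatability(self) -> float:
        tot = self.var_additive + self.var_pe + self.var_residual
        return (self.var_additive + self.var_pe) / tot


@dataclass
class QtlSpec:
    """One QTL: index into the simulated SNP map and an allele-substitution
    effect per trait (0 = no effect on that trait)."""

    snp_index: int
    effects: tuple[float, ...]


@dataclass
class SimulationConfig:
    n_founders: int = 100
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_snps: int = 1000
    n_chromosomes: int = 5
    chromosome_length_morgans: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_rate: float = 2e-6     # per-bp ancestor-switch rate
    n_ancestral_haplotypes: int = 20
    traits: tuple[TraitSpec, ...] = field(
        default_factory=lambda: tuple(TraitSpec(t) for t in DEFAULT_TRAITS)
    )
    genetic_correlation: np.ndarray | None = None  # polygenic corr, default I
    qtl: tuple[QtlSpec, ...] = ()
    n_cg: int = 25
    cg_sd: float = 0.5
    parity_levels: int = 3
    parity_sd: float = 0.1
    age_years_range: tuple[int, int] = (2, 10)
    age_slope_sd: float = 0.001     # per-day slope spread across year classes
    records_per_animal_range: tuple[int, int] = (1, 3)
    missing_trait_fraction: dict[str, float] = field(default_factory=dict)
    prop_genotyped: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be at least 2")
        if not 0.0 < self.prop_genotyped <= 1.0:
            raise ValueError("prop_genotyped must be in (0, 1]")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for q in self.qtl:
            if len(q.effects) != len(self.traits):
                raise ValueError("each QTL needs one effect per trait")
            if not all(np.isfinite(q.effects)):
                raise ValueError("QTL effects must be finite")
            if not 0 <= q.snp_index < self.n_snps:
                raise ValueError(f"QTL snp_index {q.snp_index} out of range")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]


@dataclass
class TruthSet:
    """Ground truth: per-animal true breeding values (total = polygenic +
    QTL), the QTL placement/effects, and the simulated fixed-effect values."""

    animal_ids: list[str]
    trait_names: list[str]
    tbv: np.ndarray                  # animals × traits, total genetic
    tbv_polygenic: np.ndarray
    tbv_qtl: np.ndarray
    qtl_table: pd.DataFrame          # snp_id, snp_index, chromosome, position_bp, effect per trait
    cg_effects: pd.DataFrame
    parity_effects: pd.DataFrame
    age_slopes: pd.DataFrame
    permanent_env: np.ndarray        # animals × traits


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Random-mating pedigree with non-overlapping generations.

    Founders split evenly into sires and dams; each generation draws
    ``n_founders // 2`` sire×dam matings (without selfing, by construction)
    from the previous generation, each producing ``offspring_per_mating``
    offspring whose sexes alternate.
    """
    rng = _rng(config, 1)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[int] = []  # 0 male, 1 female

    for i in range(config.n_founders):
        ids.append(f"G0_{i + 1}")
        sire.append(UNKNOWN_PARENT)
        dam.append(UNKNOWN_PARENT)
        sex.append(i % 2)
    prev = list(range(config.n_founders))

    n_matings = max(1, config.n_founders // 2)
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == 0]
        females = [i for i in prev if sex[i] == 1]
        if not males or not females:
            raise ValueError("a generation lost one sex entirely; increase n_founders")
        cur: list[int] = []
        for m in range(n_matings):
            s = males[int(rng.integers(len(males)))]
            d = females[int(rng.integers(len(females)))]
            for k in range(config.offspring_per_mating):
                idx = len(ids)
                ids.append(f"G{g}_{m + 1}_{k + 1}")
                sire.append(s)
                dam.append(d)
                sex.append(k % 2)
                cur.append(idx)
        prev = cur
    return Pedigree(ids=ids, sire=np.array(sire), dam=np.array(dam))


def make_snp_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spread SNPs across chromosomes; 1 Morgan ≡ 100 Mb physical."""
    rng = _rng(config, 2)
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    bp_length = int(config.chromosome_length_morgans * 1e8)
    rows = []
    for c in range(config.n_chromosomes):
        m = int(per_chrom[c])
        pos = np.sort(rng.choice(np.arange(1, bp_length + 1), size=m, replace=False))
        for j, p in enumerate(pos):
            rows.append((f"snp_{c + 1}_{j + 1}", c + 1, int(p)))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig, snp_map: pd.DataFrame | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Founder mosaic haplotypes plus gene dropping with Haldane recombination.

    Returns the genotype matrix over ALL pedigree animals (subset later by
    ``prop_genotyped``) and the phased haplotypes (animals × 2 × SNPs).
    """
    rng = _rng(config, 3)
    if snp_map is None:
        snp_map = make_snp_map(config)
    n_animals = len(pedigree)
    n_snps = len(snp_map)
    chroms = snp_map["chromosome"].to_numpy()
    pos = snp_map["position_bp"].to_numpy()
    bp_length = config.chromosome_length_morgans * 1e8
    morgan_pos = pos / 1e8  # 1 Morgan per 100 Mb

    haplo = np.zeros((n_animals, 2, n_snps), dtype=np.int8)
    founder_mask = (pedigree.sire == UNKNOWN_PARENT) & (pedigree.dam == UNKNOWN_PARENT)
    founders = np.flatnonzero(founder_mask)

    for c in np.unique(chroms):
        cols = np.flatnonzero(chroms == c)
        m = cols.size
        p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
        flip = rng.random(m) < 0.5  # reference allele is minor or major at random
        freq = np.where(flip, 1.0 - p, p)
        # ancestral pool
        K = config.n_ancestral_haplotypes
        pool = (rng.random((K, m)) < freq).astype(np.int8)
        # founder haplotypes: mosaic over the pool
        d = np.diff(pos[cols]).astype(float)
        switch_p = 1.0 - np.exp(-config.ld_decay_rate * d)
        n_fh = founders.size * 2
        anc = np.empty((n_fh, m), dtype=np.int64)
        anc[:, 0] = rng.integers(K, size=n_fh)
        switches = rng.random((n_fh, m - 1)) < switch_p
        new_anc = rng.integers(K, size=(n_fh, m - 1))
        for j in range(1, m):
            anc[:, j] = np.where(switches[:, j - 1], new_anc[:, j - 1], anc[:, j - 1])
        fh = pool[anc, np.arange(m)]
        for k, f in enumerate(founders):
            haplo[f, 0, cols] = fh[2 * k]
            haplo[f, 1, cols] = fh[2 * k + 1]

    # gene dropping, per chromosome blocks handled inside _meiosis
    chrom_slices = {c: np.flatnonzero(chroms == c) for c in np.unique(chroms)}
    for i in range(n_animals):
        if founder_mask[i]:
            continue
        for h, parent in enumerate((pedigree.sire[i], pedigree.dam[i])):
            haplo[i, h] = _meiosis(haplo[parent], chrom_slices, morgan_pos, config, rng)

    geno = haplo.sum(axis=1).astype(np.float64)
    gm = GenotypeMatrix(animal_ids=list(pedigree.ids), matrix=geno, snp_map=snp_map)
    return gm, haplo


def _meiosis(
    parent_haplo: np.ndarray,
    chrom_slices: dict[int, np.ndarray],
    morgan_pos: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: per chromosome, Poisson crossovers on the Morgan scale."""
    gamete = np.empty(parent_haplo.shape[1], dtype=np.int8)
    L = config.chromosome_length_morgans
    for cols in chrom_slices.values():
        n_cross = rng.poisson(L)
        current = int(rng.integers(2))
        if n_cross == 0:
            gamete[cols] = parent_haplo[current, cols]
            continue
        cross = np.sort(rng.uniform(0.0, L, size=n_cross))
        phase = (current + np.searchsorted(cross, morgan_pos[cols])) % 2
        gamete[cols] = parent_haplo[phase, cols]
    return gamete


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TruthSet]:
    """Repeated records under the repeatability model, with known truth.

    TBV = Σ_q effect_q · (genotype_q − 2p_q)  +  polygenic term, the latter
    simulated down the pedigree (parent average + Mendelian sampling with
    inbreeding-corrected variance) so var(polygenic) = σ²a by construction.
    """
    rng = _rng(config, 4)
    n = len(pedigree)
    k = len(config.traits)
    trait_names = config.trait_names

    corr = np.eye(k) if config.genetic_correlation is None else np.asarray(config.genetic_correlation)
    if corr.shape != (k, k):
        raise ValueError("genetic_correlation must be k × k")
    L_g = np.linalg.cholesky(corr)
    sd_a = np.array([t.var_additive for t in config.traits]) ** 0.5

    F = inbreeding_coefficients(pedigree)
    poly = np.zeros((n, k))
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        known = [p for p in (s, d) if p != UNKNOWN_PARENT]
        pa = sum(poly[p] for p in known) / 2.0 if known else np.zeros(k)
        if len(known) == 2:
            ms_var = 0.5 - 0.25 * (F[s] + F[d])
        elif len(known) == 1:
            ms_var = 0.75 - 0.25 * F[known[0]]
        else:
            ms_var = 1.0
        z = L_g @ rng.standard_normal(k)
        poly[i] = pa + np.sqrt(ms_var) * sd_a * z

    # QTL contributions on the same animals as the genotype matrix
    qtl_tbv = np.zeros((n, k))
    qtl_rows = []
    if config.qtl:
        geno_idx = pedigree.index_of(genotypes.animal_ids)
        if not np.array_equal(geno_idx, np.arange(n)):
            raise ValueError("phenotype simulation needs genotypes for the full pedigree")
        p_all = genotypes.allele_frequencies()
        for q in config.qtl:
            g_centered = genotypes.matrix[:, q.snp_index] - 2.0 * p_all[q.snp_index]
            for t in range(k):
                qtl_tbv[:, t] += q.effects[t] * g_centered
            row = genotypes.snp_map.iloc[q.snp_index]
            qtl_rows.append(
                (row["snp_id"], q.snp_index, row["chromosome"], row["position_bp"], *q.effects)
            )
    qtl_table = pd.DataFrame(
        qtl_rows,
        columns=["snp_id", "snp_index", "chromosome", "position_bp"]
        + [f"effect_{t}" for t in trait_names],
    )

    tbv = poly + qtl_tbv
    pe = rng.standard_normal((n, k)) * np.array([t.var_pe for t in config.traits]) ** 0.5

    cg_eff = rng.standard_normal(config.n_cg) * config.cg_sd
    parity_eff = rng.standard_normal(config.parity_levels) * config.parity_sd
    parity_eff[0] = 0.0
    year_classes = np.arange(config.age_years_range[0], config.age_years_range[1] + 1)
    age_slope = rng.standard_normal(year_classes.size) * config.age_slope_sd

    sd_e = np.array([t.var_residual for t in config.traits]) ** 0.5
    lo, hi = config.records_per_animal_range
    rows = []
    for i, animal in enumerate(pedigree.ids):
        n_rec = int(rng.integers(lo, hi + 1))
        base_year = int(rng.integers(year_classes[0], year_classes[-1] - n_rec + 2)) if year_classes[-1] - n_rec + 2 > year_classes[0] else int(year_classes[0])
        for r in range(n_rec):
            age_years = min(base_year + r, int(year_classes[-1]))
            age_days = age_years * 365.25 + float(rng.uniform(0, 365))
            cg = int(rng.integers(config.n_cg))
            parity = min(r + 1, config.parity_levels)
            yc = age_years - year_classes[0]
            fixed = cg_eff[cg] + parity_eff[parity - 1] + age_slope[yc] * age_days
            for t, tname in enumerate(trait_names):
                drop = config.missing_trait_fraction.get(tname, 0.0)
                if drop > 0 and rng.random() < drop:
                    continue
                value = fixed + tbv[i, t] + pe[i, t] + sd_e[t] * rng.standard_normal()
                rows.append(
                    (animal, tname, value, f"cg{cg + 1}", parity, age_days, age_years)
                )
    records = pd.DataFrame(
        rows, columns=["animal", "trait", "value", "cg", "parity", "age_days", "age_years"]
    )

    truth = TruthSet(
        animal_ids=list(pedigree.ids),
        trait_names=trait_names,
        tbv=tbv,
        tbv_polygenic=poly,
        tbv_qtl=qtl_tbv,
        qtl_table=qtl_table,
        cg_effects=pd.DataFrame({"cg": [f"cg{i + 1}" for i in range(config.n_cg)], "effect": cg_eff}),
        parity_effects=pd.DataFrame({"parity": np.arange(1, config.parity_levels + 1), "effect": parity_eff}),
        age_slopes=pd.DataFrame({"age_years": year_classes, "slope": age_slope}),
        permanent_env=pe,
    )
    return records, truth


def simulate_dataset(config: SimulationConfig):
    """Full bundle: pedigree (with genotyped flags), genotypes of the
    genotyped subset, phenotype records and truth."""
    ped = simulate_pedigree(config)
    geno_all, _ = simulate_genotypes(ped, config)
    records, truth = simulate_phenotypes(ped, geno_all, config)
    rng = _rng(config, 5)
    n_gen = max(2, int(round(config.prop_genotyped * len(ped))))
    # prefer later generations, as in real evaluations where young animals
    # are densely genotyped
    chosen = np.sort(rng.choice(len(ped), size=min(n_gen, len(ped)), replace=False))
    ped.set_genotyped([ped.ids[i] for i in chosen])
    genotyped = geno_all.subset(animals=chosen)
    return ped, genotyped, geno_all, records, truth
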