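"""Shared fixtures: toy pedigrees, simulated datasets, annotation files.

The expensive null-model simulation (no QTL, three independent traits, ~500
genotyped animals, 2,000 SNPs) is session-scoped and shared between the
pleiotropy property tests and the calibration acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sspleio.datatypes import Pedigree
from sspleio.mme import ModelSpec, adjusted_means_frame
from sspleio.qc import filter_genotypes
from sspleio.relmat import blend_G, build_A, build_A_inverse, build_G, build_H_inverse
from sspleio.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def four_animal_pedigree() -> Pedigree:
    """1, 2 founders; 3 = 1×2; 4 = 1×3 (inbred)."""
    return Pedigree(
        ids=["1", "2", "3", "4"],
        sire=np.array([-1, -1, 0, 0]),
        dam=np.array([-1, -1, 1, 2]),
    )


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random valid pedigree: each animal's parents drawn from predecessors
    (or unknown), guaranteeing topological order."""
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        if rng.random() < 0.7:
            sire[i] = rng.integers(i)
        if rng.random() < 0.7:
            d = int(rng.integers(i))
            if d != sire[i]:
                dam[i] = d
    return Pedigree(ids=[f"a{i}" for i in range(n)], sire=sire, dam=dam)


def _single_step_parts(ped, geno):
    """Common assembly: QC'd genotypes → A, A22, blended G, H⁻¹."""
    geno_qc, *_ = filter_genotypes(geno)
    A = build_A(ped)
    order = ped.index_of(geno_qc.animal_ids)
    A22 = A[np.ix_(order, order)]
    G = blend_G(build_G(geno_qc), A22)
    H_inv = build_H_inverse(build_A_inverse(ped), A22, G, order)
    return geno_qc, A, A22, G, H_inv, order


@pytest.fixture(scope="session")
def small_qtl_dataset():
    """~120 animals, 300 SNPs, one pleiotropic QTL: quick signal checks."""
    from sspleio.simulate import QtlSpec

    cfg = SimulationConfig(
        n_founders=40,
        n_generations=2,
        n_snps=300,
        n_chromosomes=3,
        seed=7,
        prop_genotyped=0.6,
        qtl=(QtlSpec(40, (0.35, 0.35, 0.35)),),
    )
    ped, geno, _geno_all, records, truth = simulate_dataset(cfg)
    geno_qc, A, A22, G, H_inv, order = _single_step_parts(ped, geno)
    return dict(
        config=cfg, pedigree=ped, genotypes=geno_qc, records=records,
        truth=truth, A=A, A22=A22, G=G, H_inv=H_inv,
    )


@pytest.fixture(scope="session")
def null_dataset():
    """No QTL, independent traits, ~500 genotyped animals × 2,000 SNPs —
    the null-calibration workhorse."""
    cfg = SimulationConfig(
        n_founders=334,
        n_generations=2,
        n_snps=2000,
        n_chromosomes=5,
        seed=11,
        prop_genotyped=0.5,
        n_cg=40,
    )
    ped, geno, _geno_all, records, truth = simulate_dataset(cfg)
    geno_qc, A, A22, G, H_inv, order = _single_step_parts(ped, geno)
    specs = [ModelSpec(t.name, t.var_additive, t.var_pe, t.var_residual) for t in cfg.traits]
    means, solutions = adjusted_means_frame(records, ped, specs, H_inv)
    return dict(
        config=cfg, pedigree=ped, genotypes=geno_qc, records=records,
        truth=truth, A=A, A22=A22, G=G, H_inv=H_inv,
        adjusted_means=means, solutions=solutions, specs=specs,
    )


@pytest.fixture(scope="session")
def sparse_null_dataset():
    """Null model on a sparse (low-LD) map: founder alleles effectively
    independent between adjacent SNPs, for significance-count calibration
    where binomial bounds assume near-independent tests."""
    cfg = SimulationConfig(
        n_founders=334,
        n_generations=2,
        n_snps=2000,
        n_chromosomes=5,
        ld_decay_rate=5e-5,
        seed=19,
        prop_genotyped=0.5,
        n_cg=40,
    )
    ped, geno, _geno_all, records, truth = simulate_dataset(cfg)
    geno_qc, A, A22, G, H_inv, order = _single_step_parts(ped, geno)
    return dict(
        config=cfg, pedigree=ped, genotypes=geno_qc, records=records,
        truth=truth, A=A, A22=A22, G=G, H_inv=H_inv,
        specs=[ModelSpec(t.name, t.var_additive, t.var_pe, t.var_residual) for t in cfg.traits],
    )


@pytest.fixture
def toy_gtf(tmp_path):
    """Five genes on chr1/chr2, including a duplicated gene id (union span)."""
    lines = [
        '1\tens\tgene\t100\t200\t.\t+\t.\tgene_id "g1"; gene_biotype "protein_coding";',
        '1\tens\tgene\t150000\t160000\t.\t+\t.\tgene_id "g2"; gene_biotype "lncRNA";',
        '1\tens\tgene\t250001\t260000\t.\t-\t.\tgene_id "g3"; gene_biotype "protein_coding";',
        '2\tens\tgene\t5000\t6000\t.\t+\t.\tgene_id "g4"; gene_biotype "miRNA";',
        '2\tens\tgene\t5500\t7000\t.\t+\t.\tgene_id "g4"; gene_biotype "miRNA";',
        '2\tens\tgene\t900000\t910000\t.\t+\t.\tgene_id "g5"; gene_biotype "protein_coding";',
    ]
    path = tmp_path / "genes.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_qtl_gff(tmp_path):
    """QTLdb-style GFF3 with trait terms and categories."""
    rows = [
        (1, 140000, 220000, "Q1", "Body weight", "Production"),
        (1, 100000, 400000, "Q2", "Carcass weight", "Meat and Carcass"),
        (1, 600000, 700000, "Q3", "Milk yield", "Milk"),
        (2, 4000, 8000, "Q4", "Stature", "Exterior"),
        (2, 850000, 950000, "Q5", "Body weight", "Production"),
    ]
    lines = ["##gff-version 3"]
    for chrom, s, e, qid, trait, ttype in rows:
        lines.append(
            f"{chrom}\tQTLdb\tQTL\t{s}\t{e}\t.\t.\t.\t"
            f'ID={qid};QTL_ID={qid};trait={trait};trait_type={ttype}'
        )
    path = tmp_path / "qtl.gff"
    path.write_text("\n".join(lines) + "\n")
    return path


def toy_phenotypes(rows) -> pd.DataFrame:
    """Helper: records from (animal, trait, value, cg, parity, age_years)."""
    return pd.DataFrame(
        [
            dict(
                animal=a, trait=t, value=v, cg=cg, parity=parity,
                age_days=age_years * 365.25 + 10, age_years=age_years,
            )
            for a, t, v, cg, parity, age_years in rows
        ]
    )
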