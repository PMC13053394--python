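"""Window-based gene/QTL annotation of significant SNPs and enrichment.

Each significant SNP gets a ±100 kb window (clamped at position 1, never
merged with neighbouring windows); genes and QTL-database records hit a
window when their 1-based inclusive intervals intersect on the same
chromosome. QTL trait terms are tested for over-representation among the
window-hit records against the full database background with an exact
hypergeometric upper tail, Benjamini–Hochberg corrected across terms
(enriched at FDR < 0.05), alongside the richness factor — annotated records
of a term divided by the term's background total.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneFeature, QtlFeature

#: default QTLdb major trait-category vocabulary
QTL_CATEGORIES = ("Production", "Meat and Carcass", "Health", "Milk", "Exterior", "Reproduction")


@dataclass(frozen=True)
class AnnotationWindow:
    snp_id: str
    chromosome: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end <= self.start:
            raise ValueError(f"invalid window for {self.snp_id}")


def make_windows(significant_snps: pd.DataFrame, flank: int = 100_000) -> list[AnnotationWindow]:
    """One ±flank window per SNP row (needs snp_id, chromosome, position_bp);
    the lower edge is clamped at 1, and windows are never merged."""
    out = []
    for row in significant_snps.itertuples(index=False):
        pos = int(row.position_bp)
        out.append(
            AnnotationWindow(
                snp_id=str(row.snp_id),
                chromosome=int(row.chromosome),
                start=max(1, pos - flank),
                end=pos + flank,
            )
        )
    return out


def _feature_fields(feature) -> dict:
    if isinstance(feature, GeneFeature):
        return {
            "feature_id": feature.gene_id,
            "feature_kind": "gene",
            "label": feature.biotype,
            "trait_term": "",
        }
    if isinstance(feature, QtlFeature):
        return {
            "feature_id": feature.qtl_id,
            "feature_kind": "qtl",
            "label": feature.trait_type,
            "trait_term": feature.trait_term,
        }
    raise TypeError(f"unsupported feature type {type(feature).__name__}")


def annotate(windows: list[AnnotationWindow], features: list[GeneFeature] | list[QtlFeature]) -> pd.DataFrame:
    """Window × feature intersection table (1-based inclusive overlap).

    Raises when the features' chromosomes and the windows' share no name —
    a map/annotation build mismatch rather than a true empty result.
    """
    wchroms = {w.chromosome for w in windows}
    fchroms = {f.chromosome for f in features}
    if windows and features and not (wchroms & fchroms):
        raise ValueError(
            f"no chromosome shared between windows {sorted(wchroms)} and "
            f"annotation {sorted(fchroms)}: name-space mismatch"
        )
    trees: dict[int, IntervalTree] = {}
    for f in features:
        # half-open tree coordinates: [start, end+1) ≡ 1-based inclusive
        trees.setdefault(f.chromosome, IntervalTree()).addi(f.start, f.end + 1, f)
    rows = []
    for w in windows:
        tree = trees.get(w.chromosome)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(w.start, w.end + 1)):
            f = iv.data
            overlap = min(w.end, f.end) - max(w.start, f.start) + 1
            rows.append(
                {
                    "snp_id": w.snp_id,
                    "chromosome": w.chromosome,
                    "window_start": w.start,
                    "window_end": w.end,
                    **_feature_fields(f),
                    "feature_start": f.start,
                    "feature_end": f.end,
                    "overlap_bp": overlap,
                }
            )
    cols = [
        "snp_id", "chromosome", "window_start", "window_end", "feature_id",
        "feature_kind", "label", "trait_term", "feature_start", "feature_end", "overlap_bp",
    ]
    return pd.DataFrame(rows, columns=cols)


def overlap_sets(per_trait_sets: dict[str, set]) -> pd.DataFrame:
    """Venn-region counts for 2–3 sets (every non-empty trait combination;
    each region counts elements in exactly those traits)."""
    names = list(per_trait_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 traits for overlap counting")
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(per_trait_sets[n] for n in combo))
            outside = set.union(set(), *(per_trait_sets[n] for n in names if n not in combo))
            region = inside - outside
            rows.append({"traits": "&".join(combo), "n_traits": r, "count": len(region)})
    return pd.DataFrame(rows)


def qtl_enrichment(
    hits: pd.DataFrame,
    qtl_database: list[QtlFeature],
    by: str = "trait_term",
    per_chromosome: bool = False,
    fdr_alpha: float = 0.05,
    method: str = "hypergeometric",
) -> pd.DataFrame:
    """Over-representation of QTL terms among window-hit records.

    Background = every record in the database (restricted to one chromosome
    when ``per_chromosome``); observed = window-hit records. For each term:
    hypergeometric upper-tail p = P(X ≥ observed) with X ~
    Hypergeom(N=background size, K=background term count, n=hit count),
    BH-FDR across terms, and richness factor = observed / background term
    count. ``by`` selects the grouping attribute: ``trait_term`` (the
    QTL-mapped trait) or ``trait_type`` (the six-category classification).
    ``method="chi2"`` swaps in the one-sided 2×2 chi-square approximation.
    """
    if not qtl_database:
        raise ValueError("empty QTL background")
    if by not in ("trait_term", "trait_type"):
        raise ValueError("by must be 'trait_term' or 'trait_type'")
    bg = pd.DataFrame(
        {
            "qtl_id": [q.qtl_id for q in qtl_database],
            "chromosome": [q.chromosome for q in qtl_database],
            "term": [getattr(q, by) for q in qtl_database],
        }
    )
    qtl_hits = hits[hits["feature_kind"] == "qtl"] if "feature_kind" in hits.columns else hits
    hit_ids = qtl_hits["feature_id"].unique()
    hit_bg = bg[bg["qtl_id"].isin(hit_ids)]

    groups = [(None, bg, hit_bg)]
    if per_chromosome:
        groups = [
            (c, bg[bg["chromosome"] == c], hit_bg[hit_bg["chromosome"] == c])
            for c in sorted(bg["chromosome"].unique())
        ]

    rows = []
    for chrom, bgrp, hgrp in groups:
        N = len(bgrp)
        n = len(hgrp)
        if N == 0:
            continue
        for term, K in bgrp["term"].value_counts().items():
            obs = int((hgrp["term"] == term).sum())
            if method == "hypergeometric":
                pval = float(stats.hypergeom.sf(obs - 1, N, int(K), n))
            elif method == "chi2":
                table = np.array([[obs, n - obs], [K - obs, N - n - (K - obs)]])
                if obs / max(n, 1) <= K / N:
                    pval = 1.0
                else:
                    chi2 = stats.chi2_contingency(np.clip(table, 0, None), correction=False)[0]
                    pval = float(stats.chi2.sf(chi2, df=1) / 2.0)
            else:
                raise ValueError("method must be 'hypergeometric' or 'chi2'")
            expected = n * K / N
            rows.append(
                {
                    "chromosome": chrom,
                    "term": term,
                    "observed": obs,
                    "expected": expected,
                    "background": int(K),
                    "n_hits": n,
                    "n_background": N,
                    "richness_factor": obs / K,
                    "p_value": pval,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = np.nan
    out["enriched"] = False
    # BH across terms, within chromosome when stratified
    for _, idx in out.groupby(out["chromosome"].astype(str)).groups.items():
        rej, padj, *_ = multipletests(out.loc[idx, "p_value"], alpha=fdr_alpha, method="fdr_bh")
        out.loc[idx, "fdr"] = padj
        out.loc[idx, "enriched"] = rej
    if not per_chromosome:
        out = out.drop(columns=["chromosome"])
    return out.sort_values("p_value").reset_index(drop=True)
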