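"""Window annotation, Venn overlaps and hypergeometric QTL enrichment."""
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sspleio import io as sio
from sspleio.annotation import (
    AnnotationWindow,
    annotate,
    make_windows,
    overlap_sets,
    qtl_enrichment,
)
from sspleio.datatypes import GeneFeature, QtlFeature


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


class TestWindows:
    def test_plain_arithmetic(self):
        (w,) = make_windows(_snps([("s", 1, 150_000)]))
        assert (w.start, w.end) == (50_000, 250_000)

    def test_clamped_at_one(self):
        (w,) = make_windows(_snps([("s", 1, 40_000)]))
        assert (w.start, w.end) == (1, 140_000)

    def test_overlapping_windows_not_merged(self):
        ws = make_windows(_snps([("s1", 1, 100_000), ("s2", 1, 110_000)]))
        assert len(ws) == 2
        assert ws[0].end > ws[1].start


class TestAnnotate:
    def test_exclusive_by_one_bp(self):
        w = [AnnotationWindow("s", 1, 50_000, 250_000)]
        gene = GeneFeature("g", 1, 250_001, 260_000)
        assert annotate(w, [gene]).empty

    def test_inclusive_single_bp_overlap(self):
        w = [AnnotationWindow("s", 1, 50_000, 250_000)]
        gene = GeneFeature("g", 1, 250_000, 260_000)
        hits = annotate(w, [gene])
        assert len(hits) == 1
        assert hits.loc[0, "overlap_bp"] == 1

    def test_constructed_fixture_exact_hits(self):
        windows = [
            AnnotationWindow("s1", 1, 100, 500),
            AnnotationWindow("s2", 1, 1000, 2000),
            AnnotationWindow("s3", 2, 100, 500),
        ]
        genes = [
            GeneFeature("gA", 1, 400, 600),     # hits s1
            GeneFeature("gB", 1, 500, 1100),    # hits s1 and s2
            GeneFeature("gC", 1, 3000, 4000),   # no hit
            GeneFeature("gD", 2, 90, 99),       # no hit (ends before)
            GeneFeature("gE", 2, 500, 501),     # hits s3
        ]
        hits = annotate(windows, genes)
        assert len(hits) == 4
        assert set(zip(hits["snp_id"], hits["feature_id"])) == {
            ("s1", "gA"), ("s1", "gB"), ("s2", "gB"), ("s3", "gE"),
        }

    def test_window_order_invariance(self):
        windows = [
            AnnotationWindow("s1", 1, 100, 500),
            AnnotationWindow("s2", 1, 300, 900),
        ]
        genes = [GeneFeature("g", 1, 200, 400)]
        a = annotate(windows, genes)
        b = annotate(windows[::-1], genes)
        assert set(map(tuple, a.values.tolist())) == set(map(tuple, b.values.tolist()))

    def test_chromosome_namespace_mismatch(self):
        w = [AnnotationWindow("s", 5, 1, 100)]
        with pytest.raises(ValueError, match="mismatch"):
            annotate(w, [GeneFeature("g", 9, 1, 100)])

    def test_gff_fixture_end_to_end(self, toy_qtl_gff):
        qtls = sio.read_qtl_gff(toy_qtl_gff)
        windows = make_windows(_snps([("s1", 1, 150_000), ("s2", 2, 5_000)]), flank=100_000)
        hits = annotate(windows, qtls)
        assert set(hits["feature_id"]) == {"Q1", "Q2", "Q4"}


class TestOverlapSets:
    def test_triple_intersection(self):
        counts = overlap_sets({"A": {"a", "b"}, "B": {"b", "c"}, "C": {"b"}})
        table = counts.set_index("traits")["count"]
        assert table["A&B&C"] == 1      # {b}
        assert table["A"] == 1          # {a}
        assert table["B"] == 1          # {c}
        assert table["C"] == 0

    def test_disjoint_sets(self):
        counts = overlap_sets({"A": {1}, "B": {2}, "C": {3}})
        table = counts.set_index("traits")["count"]
        assert table[["A&B", "A&C", "B&C", "A&B&C"]].sum() == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        universe = list(range(60))
        sets = {t: set(rng.choice(universe, size=24, replace=False)) for t in "XYZ"}
        counts = overlap_sets(sets).set_index("traits")["count"]
        # brute force: classify every element by its membership pattern
        brute: dict[str, int] = {}
        for e in universe:
            members = [t for t in "XYZ" if e in sets[t]]
            if members:
                key = "&".join(members)
                brute[key] = brute.get(key, 0) + 1
        for key, n in brute.items():
            assert counts[key] == n
        assert counts.sum() == len(set.union(*sets.values()))


def _hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x) / comb(N, n)
    return total


class TestEnrichment:
    def _db(self, n_term, n_other):
        qtls = [
            QtlFeature(f"T{i}", 1, 100 * i + 1, 100 * i + 50, "Body weight", "Production")
            for i in range(n_term)
        ]
        qtls += [
            QtlFeature(f"O{i}", 1, 100_000 + 100 * i, 100_000 + 100 * i + 50,
                       f"other_{i % 7}", "Milk")
            for i in range(n_other)
        ]
        return qtls

    def test_exact_tail_oracle(self):
        # background 100 records, 10 of the term; 20 hit, 10 of the term
        db = self._db(10, 90)
        hit_ids = [f"T{i}" for i in range(10)] + [f"O{i}" for i in range(10)]
        hits = pd.DataFrame({"feature_id": hit_ids, "feature_kind": "qtl"})
        out = qtl_enrichment(hits, db)
        row = out[out["term"] == "Body weight"].iloc[0]
        assert row["observed"] == 10
        assert row["p_value"] == pytest.approx(_hypergeom_tail_oracle(100, 10, 20, 10), rel=1e-10)
        assert row["richness_factor"] == pytest.approx(1.0)

    def test_null_proportion_not_enriched(self):
        db = self._db(10, 90)
        hit_ids = [f"T{i}" for i in range(2)] + [f"O{i}" for i in range(18)]
        hits = pd.DataFrame({"feature_id": hit_ids, "feature_kind": "qtl"})
        out = qtl_enrichment(hits, db)
        row = out[out["term"] == "Body weight"].iloc[0]
        assert row["p_value"] > 0.5
        assert not row["enriched"]

    def test_single_term_fdr_equals_p(self):
        db = [QtlFeature(f"T{i}", 1, i * 10 + 1, i * 10 + 5, "Stature", "Exterior")
              for i in range(20)]
        hits = pd.DataFrame({"feature_id": ["T0", "T1"], "feature_kind": "qtl"})
        out = qtl_enrichment(hits, db)
        assert out.loc[0, "fdr"] == pytest.approx(out.loc[0, "p_value"])

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        terms = [f"t{i}" for i in range(12)]
        db = [QtlFeature(f"q{i}", 1, i * 10 + 1, i * 10 + 5, terms[i % 12], "Production")
              for i in range(240)]
        chosen = rng.choice([q.qtl_id for q in db], size=60, replace=False)
        hits = pd.DataFrame({"feature_id": chosen, "feature_kind": "qtl"})
        out = qtl_enrichment(hits, db).sort_values("p_value")
        assert out["fdr"].is_monotonic_increasing
        assert (out["fdr"] <= 1.0).all()
        assert (out["fdr"] >= out["p_value"] - 1e-12).all()

    def test_permuted_background_p_uniform(self):
        # term labels shuffled against hit status: p-values should be
        # approximately uniform over repetitions
        rng = np.random.default_rng(2)
        pvals = []
        for rep in range(300):
            labels = np.array(["A"] * 25 + ["B"] * 75)
            rng.shuffle(labels)
            db = [QtlFeature(f"q{i}", 1, 10 * i + 1, 10 * i + 5, str(labels[i]), "")
                  for i in range(100)]
            hits = pd.DataFrame({"feature_id": [f"q{i}" for i in range(30)],
                                 "feature_kind": "qtl"})
            out = qtl_enrichment(hits, db)
            pvals.append(float(out.loc[out["term"] == "A", "p_value"].iloc[0]))
        # discrete p-values are conservative; check stochastic dominance of
        # the uniform rather than a two-sided KS
        pvals = np.asarray(pvals)
        for q in (0.2, 0.5, 0.8):
            assert (pvals <= q).mean() <= q + 3 * np.sqrt(q * (1 - q) / 300)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            qtl_enrichment(pd.DataFrame({"feature_id": [], "feature_kind": []}), [])

    def test_per_chromosome_stratification(self):
        db = [QtlFeature(f"c1_{i}", 1, 10 * i + 1, 10 * i + 5, "Body weight", "Production")
              for i in range(20)]
        db += [QtlFeature(f"c2_{i}", 2, 10 * i + 1, 10 * i + 5, "Body weight", "Production")
               for i in range(20)]
        hits = pd.DataFrame({"feature_id": [f"c1_{i}" for i in range(5)],
                             "feature_kind": "qtl"})
        out = qtl_enrichment(hits, db, per_chromosome=True)
        assert set(out["chromosome"]) == {1, 2}

    def test_trait_type_grouping(self, toy_qtl_gff):
        qtls = sio.read_qtl_gff(toy_qtl_gff)
        hits = pd.DataFrame({"feature_id": ["Q1", "Q5"], "feature_kind": "qtl"})
        out = qtl_enrichment(hits, qtls, by="trait_type")
        assert "Production" in set(out["term"])
        row = out[out["term"] == "Production"].iloc[0]
        assert row["observed"] == 2 and row["background"] == 2
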