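"""Age x bias tables, branch profiles, cluster pooling, feature proximity."""

import numpy as np
import pandas as pd
import pytest

from genebirth.enrichment import (EnrichmentError, bias_table, branch_profile,
                                  cluster_bias_table, feature_association,
                                  pool_clusters, term_enrichment)

from conftest import binom_two_sided_oracle, fisher_two_sided_oracle, make_catalog


def calls_frame(pairs):
    return pd.DataFrame(pairs, columns=["gene_id", "direction"])


class TestBiasTable:
    def _setup(self, young_early, young_late, old_early, old_late):
        rows, ages = [], []
        i = 0
        for n, age, d in [(young_early, "young", "early"), (young_late, "young", "late"),
                          (old_early, "old", "early"), (old_late, "old", "late")]:
            for _ in range(n):
                rows.append((f"g{i}", d)); ages.append(age); i += 1
        catalog = make_catalog([r[0] for r in rows], ages=ages)
        return calls_frame(rows), catalog

    def test_fet_matches_enumeration(self):
        calls, catalog = self._setup(30, 10, 500, 520)
        bt = bias_table(calls, catalog)
        assert bt.p == pytest.approx(fisher_two_sided_oracle(30, 10, 500, 520), abs=1e-12)

    def test_equal_proportions(self):
        calls, catalog = self._setup(10, 10, 40, 40)
        assert bias_table(calls, catalog).p == 1.0

    def test_unbiased_genes_excluded(self):
        calls, catalog = self._setup(5, 5, 5, 5)
        calls = pd.concat([calls, calls_frame([("g0", "unbiased")])]).drop_duplicates("gene_id", keep="last")
        with_unbiased = bias_table(calls, catalog)
        assert int(with_unbiased.counts.to_numpy().sum()) == 19

    def test_empty_margin_rejected(self):
        calls, catalog = self._setup(5, 5, 0, 0)
        with pytest.raises(EnrichmentError, match="empty margin"):
            bias_table(calls, catalog)


class TestBranchProfile:
    def _profile(self, ups, downs, branch=1, n_branches=2):
        genes = [f"g{i}" for i in range(ups + downs)]
        calls = calls_frame([(g, "up" if i < ups else "down")
                             for i, g in enumerate(genes)])
        catalog = make_catalog(genes, branches=[branch] * len(genes))
        return branch_profile(calls, catalog, n_branches, "up", "down")

    def test_balanced_branch(self):
        prof = self._profile(10, 10)
        assert prof.loc[1, "binom_p"] == 1.0

    def test_nine_one_exact_p(self):
        prof = self._profile(9, 1)
        assert prof.loc[1, "binom_p"] == pytest.approx(11 / 512, abs=1e-12)
        assert prof.loc[1, "binom_p"] == pytest.approx(
            binom_two_sided_oracle(9, 10), abs=1e-12)

    def test_counts_partition(self):
        prof = self._profile(6, 3)
        row = prof.loc[1]
        assert row["n_up"] + row["n_down"] <= row["n_genes"]

    def test_empty_branch_flagged(self):
        prof = self._profile(4, 2, branch=0, n_branches=3)
        assert not prof.loc[2, "testable"]
        assert np.isnan(prof.loc[2, "binom_p"])

    def test_bonferroni_family_is_testable_branches(self):
        prof = self._profile(9, 1, branch=1, n_branches=5)
        m = int(prof["testable"].sum())
        assert prof.loc[1, "bonferroni_p"] == pytest.approx(
            min(1.0, prof.loc[1, "binom_p"] * m))


def biased_catalog(rows):
    """rows: (gene, chrom, start, end, branch, direction)"""
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end",
                                     "branch", "direction"])
    return df


def chaining_oracle(catalog, cutoff):
    """Independent chaining count: pairwise merge decisions then union-find."""
    parent = {g: g for g in catalog["gene_id"]}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for chrom, sub in catalog.groupby("chromosome"):
        sub = sub.sort_values(["start", "end", "gene_id"])
        rows = list(sub.itertuples())
        for a, b in zip(rows, rows[1:]):
            if (a.branch == b.branch and a.direction == b.direction
                    and b.start - a.end <= cutoff):
                parent[find(b.gene_id)] = find(a.gene_id)
    return len({find(g) for g in catalog["gene_id"]})


class TestPoolClusters:
    def test_gap_within_cutoff_merges(self):
        cat = biased_catalog([("a", "chr1", 0, 1000, 9, "early"),
                              ("b", "chr1", 50_000, 51_000, 9, "early")])
        assert len(pool_clusters(cat, 100_000)) == 1

    def test_different_bias_never_merges(self):
        cat = biased_catalog([("a", "chr1", 0, 1000, 9, "early"),
                              ("b", "chr1", 50_000, 51_000, 9, "late")])
        assert len(pool_clusters(cat, 100_000)) == 2

    def test_three_gene_chain_cutoff_dependence(self):
        cat = biased_catalog([
            ("a", "chr1", 0, 1000, 9, "early"),
            ("b", "chr1", 81_000, 82_000, 9, "early"),    # gap 80 kb
            ("c", "chr1", 172_000, 173_000, 9, "early"),  # gap 90 kb
        ])
        wide = pool_clusters(cat, 100_000)
        assert len(wide) == 1 and wide.iloc[0]["n_genes"] == 3
        narrow = pool_clusters(cat, 85_000)
        assert sorted(narrow["n_genes"]) == [1, 2]
        assert set(narrow.iloc[0]["members"].split(",")) == {"a", "b"}

    def test_overlapping_genes_merge(self):
        cat = biased_catalog([("a", "chr1", 0, 5000, 2, "late"),
                              ("b", "chr1", 3000, 8000, 2, "late")])
        assert len(pool_clusters(cat, 0)) == 1

    def test_order_invariance_and_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 60))
            rows = []
            for i in range(n):
                s = int(rng.integers(0, 500_000))
                rows.append((f"g{i}", f"chr{rng.integers(1, 3)}", s,
                             s + int(rng.integers(100, 5000)),
                             int(rng.integers(0, 3)), rng.choice(["early", "late"])))
            cat = biased_catalog(rows)
            cutoff = int(rng.integers(0, 100_000))
            shuffled = cat.sample(frac=1.0, random_state=0)
            assert len(pool_clusters(cat, cutoff)) == len(pool_clusters(shuffled, cutoff))
            assert len(pool_clusters(cat, cutoff)) == chaining_oracle(cat, cutoff)

    def test_cluster_count_monotone_in_cutoff(self, rng):
        rows = []
        for i in range(80):
            s = int(rng.integers(0, 2_000_000))
            rows.append((f"g{i}", "chr1", s, s + 1000,
                         int(rng.integers(0, 2)), rng.choice(["early", "late"])))
        cat = biased_catalog(rows)
        counts = [len(pool_clusters(cat, c)) for c in (0, 10_000, 100_000, 1_000_000)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_unbiased_rows_rejected(self):
        cat = biased_catalog([("a", "chr1", 0, 100, 1, "unbiased")])
        with pytest.raises(EnrichmentError):
            pool_clusters(cat, 1000)

    def test_cluster_level_fet(self):
        rows = []
        for i in range(12):
            rows.append((f"y{i}", "chr1", i * 10_000_000, i * 10_000_000 + 1000,
                         9, "early" if i < 10 else "late"))
        for i in range(20):
            rows.append((f"o{i}", "chr2", i * 10_000_000, i * 10_000_000 + 1000,
                         0, "early" if i < 10 else "late"))
        bt = cluster_bias_table(biased_catalog(rows), 100_000,
                                lambda b: "young" if b >= 8 else "old")
        assert int(bt.counts.to_numpy().sum()) == 32  # far apart: every gene its own cluster


class TestFeatureAssociation:
    def _catalog(self):
        cat = make_catalog(["g1", "g2"], ages=["young", "old"], spacing=1_000_000)
        cat["direction"] = ["early", "late"]
        return cat

    def test_overlapping_feature_counts_at_zero_cutoff(self):
        features = pd.DataFrame({"chromosome": ["chr1"], "start": [100], "end": [200]})
        out = feature_association(self._catalog(), features, cutoff_bp=0)
        assert out[out["age_class"] == "young"]["fraction"].iloc[0] == 1.0

    def test_strict_distance_boundary(self):
        # g1 spans [0, 1000); a feature starting at 11001 is 10001 bp away
        features = pd.DataFrame({"chromosome": ["chr1"], "start": [11_001], "end": [11_101]})
        near = feature_association(self._catalog(), features, cutoff_bp=10_001)
        far = feature_association(self._catalog(), features, cutoff_bp=10_000)
        assert near[near["age_class"] == "young"]["fraction"].iloc[0] == 1.0
        assert far[far["age_class"] == "young"]["fraction"].iloc[0] == 0.0

    def test_uniform_null_matches_geometry(self, rng):
        """Random features: association rate ~ 1 - (1 - (L + 2c)/G)^m."""
        genome, span, cutoff, m = 10_000_000, 1000, 5000, 30
        n_genes = 300
        starts = rng.integers(cutoff, genome - cutoff - span, size=n_genes)
        cat = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_genes)],
                            "chromosome": "chr1", "start": starts,
                            "end": starts + span, "age_class": "old",
                            "direction": "early"})
        fstart = rng.integers(0, genome, size=m)
        feats = pd.DataFrame({"chromosome": "chr1", "start": fstart, "end": fstart + 1})
        out = feature_association(cat, feats, cutoff_bp=cutoff)
        expected = 1 - (1 - (span + 2 * cutoff) / genome) ** m
        assert out["fraction"].iloc[0] == pytest.approx(expected, abs=0.06)

    def test_negative_cutoff_rejected(self):
        with pytest.raises(EnrichmentError):
            feature_association(self._catalog(), pd.DataFrame(
                {"chromosome": [], "start": [], "end": []}), cutoff_bp=-1)


class TestTermEnrichment:
    def test_fold_arithmetic(self):
        background = {f"g{i}" for i in range(100)}
        gene_list = {f"g{i}" for i in range(10)}
        term_map = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                                 "term": ["T"] * 10})
        # 4 of the 10 term genes in the list, 10 in the background of 100
        term_map = pd.DataFrame({
            "gene_id": [f"g{i}" for i in (0, 1, 2, 3, 40, 41, 42, 43, 44, 45)],
            "term": ["T"] * 10})
        out = term_enrichment(gene_list, background, term_map)
        assert out.loc[0, "fold_enrichment"] == pytest.approx(4.0)

    def test_list_equals_background(self):
        background = {f"g{i}" for i in range(30)}
        term_map = pd.DataFrame({"gene_id": list(background)[:12], "term": "T"})
        out = term_enrichment(background, background, term_map)
        assert out.loc[0, "fold_enrichment"] == pytest.approx(1.0)
        assert out.loc[0, "p"] == 1.0

    def test_planted_enrichment_recovered(self, rng):
        background = {f"g{i}" for i in range(2000)}
        # term covers 10% of the background but 40% of the list
        gene_list = {f"g{i}" for i in range(200)}
        term_genes = [f"g{i}" for i in range(80)] + \
                     [f"g{i}" for i in rng.integers(200, 2000, size=120)]
        term_map = pd.DataFrame({"gene_id": sorted(set(term_genes)), "term": "T"})
        other = pd.DataFrame({"gene_id": [f"g{i}" for i in range(0, 2000, 3)],
                              "term": "U"})
        out = term_enrichment(gene_list, background, pd.concat([term_map, other]))
        row = out.set_index("term").loc["T"]
        assert row["enriched"] and row["fold_enrichment"] > 2.0

    def test_orphan_term_rejected(self):
        with pytest.raises(EnrichmentError, match="no background"):
            term_enrichment({"g1"}, {"g1", "g2"},
                            pd.DataFrame({"gene_id": ["gX"], "term": ["T"]}))

    def test_list_not_subset_rejected(self):
        with pytest.raises(EnrichmentError):
            term_enrichment({"alien"}, {"g1"},
                            pd.DataFrame({"gene_id": ["g1"], "term": ["T"]}))
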