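"""Hit retention, LCA assignment, abundance tables, ordination, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plastisphere.taxonomy import (
    AbundanceTable,
    LCATaxonomyClassifier,
    Taxonomy,
    assign_reads,
    blacklist_filter,
    clade_group_test,
    clade_table,
    family_richness,
    lca_assign,
    mean_top_identity,
    retain_hits,
    round_half_away,
    round_normalize,
    sqrt_bray_nmds,
)
from plastisphere.synthetic import gen_hit_table


def hits_frame(rows):
    base = {"pident": 99.0, "length": 150, "sstart": 1, "send": 150}
    return pd.DataFrame([{**base, **r} for r in rows])


@pytest.fixture
def toy_taxonomy():
    return Taxonomy(
        lineages={
            "B1": ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                   "Rhodobacterales", "Rhodobacteraceae", "Ruegeria"),
            "B2": ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                   "Rhodobacterales", "Rhodobacteraceae", "Sulfitobacter"),
            "B3": ("Bacteria", "Cyanobacteria", "Cyanophyceae",
                   "Oscillatoriales", "Microcoleaceae", "Phormidium"),
            "E1": ("Eukaryota", "Bryozoa", "Gymnolaemata",
                   "Cheilostomatida", "Membraniporidae", "Jellyella"),
            "BAD": ("Bacteria", "Proteobacteria"),
        },
        blacklist={"BAD"},
        masks={"B3": [(100, 200)]},
    )


class TestRetainHits:
    def test_window_threshold_arithmetic(self):
        hits = hits_frame(
            [
                {"qseqid": "r", "sseqid": "a", "bitscore": 500.0},
                {"qseqid": "r", "sseqid": "b", "bitscore": 496.0},
                {"qseqid": "r", "sseqid": "c", "bitscore": 495.0},
                {"qseqid": "r", "sseqid": "d", "bitscore": 494.0},
            ]
        )
        kept = retain_hits(hits)
        assert set(kept["sseqid"]) == {"a", "b", "c"}  # >= 0.99 x 500 = 495

    def test_single_qualifying_hit_is_its_own_best(self):
        hits = hits_frame([{"qseqid": "r", "sseqid": "a", "bitscore": 60.0}])
        assert len(retain_hits(hits)) == 1

    def test_length_floor_trumps_score(self):
        hits = hits_frame(
            [{"qseqid": "r", "sseqid": "a", "bitscore": 600.0, "length": 99}]
        )
        assert len(retain_hits(hits)) == 0

    def test_bit_floor(self):
        hits = hits_frame([{"qseqid": "r", "sseqid": "a", "bitscore": 49.9}])
        assert len(retain_hits(hits)) == 0

    def test_empty_input_gives_empty_output(self):
        empty = hits_frame([]).iloc[0:0]
        assert len(retain_hits(empty)) == 0

    @given(
        st.lists(st.floats(50.0, 1000.0), min_size=1, max_size=20),
        st.randoms(use_true_random=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_order_invariant_idempotent_and_keeps_best(self, scores, rnd):
        hits = hits_frame(
            [{"qseqid": "r", "sseqid": f"s{i}", "bitscore": b}
             for i, b in enumerate(scores)]
        )
        shuffled = hits.sample(frac=1.0, random_state=rnd.randint(0, 10**6))
        kept = retain_hits(hits)
        kept_shuffled = retain_hits(shuffled)
        assert set(kept["sseqid"]) == set(kept_shuffled["sseqid"])
        assert set(retain_hits(kept)["sseqid"]) == set(kept["sseqid"])
        assert hits.loc[hits["bitscore"].idxmax(), "sseqid"] in set(kept["sseqid"])


class TestBlacklistAndMask:
    def test_blacklisted_subject_removed(self, toy_taxonomy):
        hits = hits_frame([{"qseqid": "r", "sseqid": "BAD", "bitscore": 100.0}])
        assert len(blacklist_filter(hits, toy_taxonomy)) == 0

    def test_empty_blacklist_is_identity(self, toy_taxonomy):
        tax = Taxonomy(lineages=dict(toy_taxonomy.lineages))
        hits = hits_frame([{"qseqid": "r", "sseqid": "B1", "bitscore": 100.0}])
        assert len(blacklist_filter(hits, tax)) == 1

    def test_hit_overlapping_masked_interval_removed(self, toy_taxonomy):
        overlapping = hits_frame(
            [{"qseqid": "r", "sseqid": "B3", "bitscore": 100.0,
              "sstart": 10, "send": 120}]
        )
        clear = hits_frame(
            [{"qseqid": "r", "sseqid": "B3", "bitscore": 100.0,
              "sstart": 10, "send": 99}]
        )
        assert len(blacklist_filter(overlapping, toy_taxonomy)) == 0
        assert len(blacklist_filter(clear, toy_taxonomy)) == 1

    def test_reverse_strand_coordinates_normalized(self, toy_taxonomy):
        hits = hits_frame(
            [{"qseqid": "r", "sseqid": "B3", "bitscore": 100.0,
              "sstart": 120, "send": 10}]
        )
        assert len(blacklist_filter(hits, toy_taxonomy)) == 0


class TestLCAAssign:
    def test_same_family_different_genus_assigned_to_family(self, toy_taxonomy):
        hits = hits_frame(
            [
                {"qseqid": "r", "sseqid": "B1", "bitscore": 500.0},
                {"qseqid": "r", "sseqid": "B2", "bitscore": 499.0},
            ]
        )
        a = lca_assign(retain_hits(hits), toy_taxonomy)
        assert a.lineage[-1] == "Rhodobacteraceae"
        assert a.rank_achieved == "family"
        assert len(a.lineage) == 5  # no genus

    def test_single_hit_gets_full_lineage(self, toy_taxonomy):
        hits = hits_frame([{"qseqid": "r", "sseqid": "B1", "bitscore": 500.0}])
        a = lca_assign(retain_hits(hits), toy_taxonomy)
        assert a.lineage == toy_taxonomy.lineages["B1"]
        assert a.rank_achieved == "genus"

    def test_cross_domain_hits_unclassified_root(self, toy_taxonomy):
        hits = hits_frame(
            [
                {"qseqid": "r", "sseqid": "B1", "bitscore": 500.0},
                {"qseqid": "r", "sseqid": "E1", "bitscore": 500.0},
            ]
        )
        a = lca_assign(hits, toy_taxonomy)
        assert a.lineage == ()
        assert a.rank_achieved == "root"

    def test_top_hit_identity_carried(self, toy_taxonomy):
        hits = hits_frame(
            [
                {"qseqid": "r", "sseqid": "B1", "bitscore": 500.0, "pident": 97.2},
                {"qseqid": "r", "sseqid": "B2", "bitscore": 498.0, "pident": 91.0},
            ]
        )
        assert lca_assign(hits, toy_taxonomy).top_pident == 97.2

    def test_missing_subject_skip_or_fail(self, toy_taxonomy):
        hits = hits_frame(
            [
                {"qseqid": "r", "sseqid": "B1", "bitscore": 500.0},
                {"qseqid": "r", "sseqid": "UNKNOWN", "bitscore": 499.0},
            ]
        )
        with pytest.raises(KeyError):
            lca_assign(hits, toy_taxonomy, on_missing="fail")
        a = lca_assign(hits, toy_taxonomy, on_missing="skip")
        assert a.rank_achieved == "genus"

    def test_duplicate_hits_do_not_change_assignment(self, toy_taxonomy):
        hits = hits_frame(
            [
                {"qseqid": "r", "sseqid": "B1", "bitscore": 500.0},
                {"qseqid": "r", "sseqid": "B2", "bitscore": 499.0},
            ]
        )
        doubled = pd.concat([hits, hits], ignore_index=True)
        assert (
            lca_assign(hits, toy_taxonomy).lineage
            == lca_assign(doubled, toy_taxonomy).lineage
        )

    def test_lca_never_deeper_than_shallowest_lineage(self, toy_taxonomy):
        tax = Taxonomy(lineages=dict(toy_taxonomy.lineages))
        hits = hits_frame(
            [
                {"qseqid": "r", "sseqid": "B1", "bitscore": 500.0},
                {"qseqid": "r", "sseqid": "BAD", "bitscore": 500.0},  # depth-2 lineage
            ]
        )
        a = lca_assign(hits, tax)
        assert len(a.lineage) <= 2


class TestSyntheticTruthOracle:
    def test_lca_matches_generating_truth_per_read(self):
        # constructed confounders: a sister genus inside the 1% window caps
        # the truthful rank at family; one outside must be ignored entirely
        hits, taxonomy, truth = gen_hit_table(
            reads_per_sample=400, seed=12, samples=("s1",)
        )
        clf = LCATaxonomyClassifier().fit(taxonomy)
        got = clf.predict(hits).set_index("read_id")
        want = truth.set_index("read_id")
        assert (got.loc[want.index, "lineage"] == want["true_lineage"]).all()


class TestCladeTable:
    def make_assignments(self):
        rows = []
        for i in range(6):
            rows.append({"read_id": f"a{i}", "sample": "s1",
                         "lineage": "Bacteria;P;C;O;F1;G1",
                         "rank_achieved": "genus", "top_pident": 95.0})
        for i in range(4):
            rows.append({"read_id": f"b{i}", "sample": "s1",
                         "lineage": "Bacteria;P;C;O;F2",
                         "rank_achieved": "family", "top_pident": 92.0})
        rows.append({"read_id": "c0", "sample": "s1",
                     "lineage": "Bacteria;P;C",
                     "rank_achieved": "class", "top_pident": 90.0})
        rows.append({"read_id": "d0", "sample": "s1", "lineage": "",
                     "rank_achieved": "root", "top_pident": np.nan})
        return pd.DataFrame(rows)

    def test_counts_and_rank_exclusion(self):
        table = clade_table(self.make_assignments(), rank="family")
        assert table.counts.loc["F1", "s1"] == 6
        assert table.counts.loc["F2", "s1"] == 4
        # class-only and unassigned reads are excluded from a family table
        assert table.counts["s1"].sum() == 10

    def test_denominator_modes(self):
        a = self.make_assignments()
        assert clade_table(a, "family", "rank_assigned").denominators["s1"] == 10
        assert clade_table(a, "family", "domain").denominators["s1"] == 11
        assert clade_table(a, "family", "total").denominators["s1"] == 12

    def test_proportions_under_rank_assigned_denominator(self):
        table = clade_table(self.make_assignments(), rank="family")
        assert table.proportions.loc["F1", "s1"] == pytest.approx(0.6)
        assert table.proportions.loc["F2", "s1"] == pytest.approx(0.4)

    def test_single_clade_proportion_one(self):
        df = self.make_assignments()
        table = clade_table(df[df["lineage"].str.contains("F1")], rank="family")
        assert table.proportions.loc["F1", "s1"] == 1.0

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            clade_table(self.make_assignments(), rank="species")

    def test_domain_restriction(self):
        df = self.make_assignments()
        euk = pd.DataFrame(
            [{"read_id": "e0", "sample": "s1",
              "lineage": "Eukaryota;Q;R;S;T", "rank_achieved": "family",
              "top_pident": 88.0}]
        )
        table = clade_table(pd.concat([df, euk]), rank="family", domain="Bacteria")
        assert "T" not in table.counts.index
        assert table.denominators["s1"] == 10


class TestRounding:
    def test_below_resolution_becomes_zero(self):
        assert round_half_away(0.0004, 3) == 0.0

    def test_half_away_from_zero(self):
        assert round_half_away(0.4567, 2) == pytest.approx(0.46)
        assert round_half_away(0.005, 2) == pytest.approx(0.01)  # not bankers'

    def test_rounded_value_within_half_resolution_of_truth(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        assert np.all(np.abs(round_half_away(p, 3) - p) <= 0.5e-3 + 1e-12)

    def test_round_normalize_metadata_and_errors(self):
        counts = pd.DataFrame({"s1": [6, 4]}, index=["F1", "F2"])
        table = AbundanceTable(counts=counts, denominators=pd.Series({"s1": 10.0}),
                               rank="family", denominator_mode="rank_assigned")
        round_normalize(table, 2)
        assert table.decimals == 2
        assert table.normalized.loc["F1", "s1"] == 0.6
        with pytest.raises(ValueError):
            round_normalize(table, 0)

    def test_column_sums_close_to_one_after_rounding(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(40, 6)),
            index=[f"F{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
        table = AbundanceTable(counts=counts, denominators=counts.sum(axis=0).astype(float),
                               rank="family", denominator_mode="rank_assigned")
        round_normalize(table, 3)
        sums = table.normalized.sum(axis=0)
        assert np.all(np.abs(sums - 1.0) <= 40 * 0.5e-3)


class TestNMDS:
    def test_duplicate_samples_have_zero_distance(self):
        from scipy.spatial.distance import braycurtis

        assert braycurtis(np.sqrt([4.0, 1.0]), np.sqrt([4.0, 1.0])) == 0.0

    def test_disjoint_samples_have_distance_one(self):
        from scipy.spatial.distance import braycurtis

        assert braycurtis(np.sqrt([4.0, 0.0]), np.sqrt([0.0, 4.0])) == 1.0

    def test_bray_curtis_by_hand(self):
        from scipy.spatial.distance import braycurtis

        # BC({1,1},{1,0}) = 1 - 2*1/3 = 1/3 without transform
        assert braycurtis([1.0, 1.0], [1.0, 0.0]) == pytest.approx(1.0 / 3.0)

    def test_embedding_reproducible_and_separates_groups(self):
        rng = np.random.default_rng(8)
        a = rng.dirichlet([10, 1, 1, 1], size=4)
        b = rng.dirichlet([1, 1, 10, 10], size=4)
        mat = pd.DataFrame(np.vstack([a, b]),
                           index=[f"s{i}" for i in range(8)])
        coords1, stress1 = sqrt_bray_nmds(mat, seed=3)
        coords2, stress2 = sqrt_bray_nmds(mat, seed=3)
        pd.testing.assert_frame_equal(coords1, coords2)
        assert stress1 == stress2
        centroid_gap = np.linalg.norm(
            coords1.iloc[:4].mean() - coords1.iloc[4:].mean()
        )
        within = coords1.iloc[:4].std().mean() + coords1.iloc[4:].std().mean()
        assert centroid_gap > within

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            sqrt_bray_nmds(pd.DataFrame(np.ones((2, 4))))


class TestRichnessAndGroupTest:
    def make_table(self, vals, samples):
        df = pd.DataFrame(vals, columns=samples)
        return AbundanceTable(counts=df, denominators=pd.Series(1.0, index=samples),
                              rank="family", denominator_mode="rank_assigned",
                              normalized=df)

    def test_threshold_count(self):
        table = self.make_table({"s1": [0.60, 0.30, 0.05, 0.009]}, ["s1"])
        assert family_richness(table)["s1"] == 3

    def test_all_zero_sample_zero_richness(self):
        table = self.make_table({"s1": [0.0, 0.0]}, ["s1"])
        assert family_richness(table)["s1"] == 0

    def test_planted_richness_difference_detected_by_welch(self):
        rng = np.random.default_rng(21)
        n_a, n_b, n_clades = 12, 17, 30
        cols = {}
        for i in range(n_a):  # plastic-like: ~20 families above threshold
            v = np.zeros(n_clades)
            present = rng.choice(n_clades, 20, replace=False)
            v[present] = rng.uniform(0.02, 0.1, 20)
            cols[f"p{i}"] = v
        for i in range(n_b):  # planktonic-like: ~8 families
            v = np.zeros(n_clades)
            present = rng.choice(n_clades, 8, replace=False)
            v[present] = rng.uniform(0.02, 0.1, 8)
            cols[f"w{i}"] = v
        table = self.make_table(cols, list(cols))
        groups = {s: ("plastic" if s.startswith("p") else "plankton") for s in cols}
        richness, result = family_richness(table, groups=groups)
        assert result["p"] < 0.001
        assert result["ci_low"] <= result["mean_a"] - result["mean_b"] <= result["ci_high"] \
            or result["ci_low"] <= result["mean_b"] - result["mean_a"] <= result["ci_high"]

    def test_fully_separated_clade_flagged_at_strict_fdr(self):
        rng = np.random.default_rng(3)
        n_a, n_b = 12, 17
        base = rng.uniform(0.0, 0.05, size=(30, n_a + n_b)).round(2)
        base[0, :n_a] = np.linspace(0.10, 0.30, n_a).round(2)
        base[0, n_a:] = 0.0
        samples = [f"p{i}" for i in range(n_a)] + [f"w{i}" for i in range(n_b)]
        table = self.make_table(
            {s: base[:, j] for j, s in enumerate(samples)}, samples
        )
        groups = {s: ("plastic" if s.startswith("p") else "plankton") for s in samples}
        res = clade_group_test(table, groups, fdr=0.005)
        assert bool(res.iloc[0]["significant"])

    def test_constant_clade_never_flagged(self):
        samples = [f"s{i}" for i in range(8)]
        vals = {s: [0.5, 0.1 * (i % 2)] for i, s in enumerate(samples)}
        table = self.make_table(vals, samples)
        groups = {s: ("a" if i < 4 else "b") for i, s in enumerate(samples)}
        res = clade_group_test(table, groups)
        assert res.iloc[0]["p"] == 1.0
        assert not bool(res.iloc[0]["significant"])

    def test_null_table_rarely_flagged(self):
        rng = np.random.default_rng(17)
        flagged = 0
        for _ in range(20):
            vals = rng.uniform(0, 0.1, size=(100, 29)).round(2)
            samples = [f"s{i}" for i in range(29)]
            table = self.make_table({s: vals[:, j] for j, s in enumerate(samples)},
                                    samples)
            groups = {s: ("a" if i < 12 else "b") for i, s in enumerate(samples)}
            flagged += clade_group_test(table, groups, fdr=0.005)["significant"].sum()
        assert flagged / (20 * 100) < 0.005


class TestMeanTopIdentity:
    def make_assignments(self):
        return pd.DataFrame(
            [
                {"read_id": "r1", "sample": "s1", "lineage": "Bacteria;P;C;O;F1",
                 "rank_achieved": "family", "top_pident": 90.0},
                {"read_id": "r2", "sample": "s1", "lineage": "Bacteria;P;C;O;F1;G1",
                 "rank_achieved": "genus", "top_pident": 100.0},
                {"read_id": "r3", "sample": "s2", "lineage": "Bacteria;P;C;O;F1",
                 "rank_achieved": "family", "top_pident": 97.2},
            ]
        )

    def test_single_read(self):
        assert mean_top_identity(self.make_assignments(), "F1", "s2") == 97.2

    def test_mean_over_clade_members(self):
        assert mean_top_identity(self.make_assignments(), "F1", "s1") == 95.0

    def test_constancy_across_partitions(self):
        df = self.make_assignments().assign(top_pident=93.0)
        assert mean_top_identity(df, "F1") == 93.0
        assert mean_top_identity(df, "Bacteria") == 93.0

    def test_empty_clade_reported_missing(self):
        with pytest.warns(UserWarning):
            out = mean_top_identity(self.make_assignments(), "F9")
        assert np.isnan(out)


class TestClassifierInterface:
    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            LCATaxonomyClassifier().predict(hits_frame([]))

    def test_get_set_params(self):
        clf = LCATaxonomyClassifier(window=0.02)
        assert clf.get_params()["window"] == 0.02
        clf.set_params(min_len=80)
        assert clf.min_len == 80

    def test_roundtrip_hit_table_io(self, tmp_path, toy_taxonomy):
        from plastisphere.taxonomy import read_hit_table

        hits, taxonomy, _ = gen_hit_table(reads_per_sample=25, seed=5)
        path = tmp_path / "hits.tsv"
        hits.to_csv(path, sep="\t", index=False)
        back = read_hit_table(path)
        pd.testing.assert_frame_equal(back, hits)

    def test_headerless_outfmt6_reader(self, tmp_path):
        from plastisphere.taxonomy import read_hit_table

        path = tmp_path / "hits.tsv"
        path.write_text("r1\tS1\t99.0\t150\t1\t0\t1\t150\t1\t150\t1e-30\t250\n")
        df = read_hit_table(path)
        assert df.loc[0, "sseqid"] == "S1"
        assert df.loc[0, "bitscore"] == 250
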