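"""Rule mining: transactions, closed itemsets, scoring and selection."""

import math

import numpy as np
import pytest

from amogel.arm import (ClassAssociationRule, GeneStats, Item, TransactionDB,
                        build_transactions, cba_prune, gene_stats, generate_cars,
                        iterative_min_support_search, load_rules,
                        mine_closed_frequent_itemsets, save_rules, score_car,
                        select_top_k, selected_genes, support)
from amogel.io_formats import OmicsType
from amogel.preprocess import DiscretizedDataset, SplitSpec
from conftest import brute_force_closed_itemsets, random_transaction_db


def items(*specs):
    return frozenset(Item(f, l) for f, l in specs)


def db_from(sets, label="c"):
    return TransactionDB(label, [frozenset(s) for s in sets])


A, B, C = Item("a", 0), Item("b", 0), Item("c", 0)


def tiny_dds():
    """4 train + 2 test samples, 2 features, 2 classes."""
    levels = np.array([[2, 0], [2, 0], [0, 2], [0, 2], [2, 0], [0, 2]], dtype=np.int8)
    uids = ["mRNA:g1", "mRNA:g2"]
    return DiscretizedDataset(
        [f"s{i}" for i in range(6)], ["x", "x", "y", "y", "x", "y"], uids,
        levels, np.zeros((2, 2)), {u: OmicsType.MRNA for u in uids})


def tiny_split():
    return SplitSpec([f"s{i}" for i in range(4)], ["s4", "s5"], seed=0)


class TestTransactions:
    def test_one_transaction_per_training_sample(self):
        db = build_transactions(tiny_dds(), tiny_split(), "x")
        assert db.n == 2
        assert all(len(t) == 2 for t in db.transactions)

    def test_items_are_feature_level_pairs(self):
        db = build_transactions(tiny_dds(), tiny_split(), "x")
        assert db.transactions[0] == items(("mRNA:g1", 2), ("mRNA:g2", 0))

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            build_transactions(tiny_dds(), tiny_split(), "nope")


class TestSupport:
    def test_fraction_of_matching_transactions(self):
        db = db_from([{A, B}, {A}, {A, B}, {B}])
        assert support(frozenset({A}), db) == 0.75
        assert support(frozenset({A, B}), db) == 0.5

    def test_no_match_is_zero(self):
        db = db_from([{A}, {B}])
        assert support(frozenset({C}), db) == 0.0

    def test_unique_full_transaction(self):
        db = db_from([{A, B}, {A, C}, {B, C}])
        assert support(frozenset({A, B}), db) == pytest.approx(1 / 3)

    def test_empty_itemset_raises(self):
        with pytest.raises(ValueError):
            support(frozenset(), db_from([{A}]))


class TestClosedItemsets:
    def test_documented_three_transaction_example(self):
        db = db_from([{A, B}, {A}, {A, B}])
        got = dict(mine_closed_frequent_itemsets(db, 0.5))
        assert got == {frozenset({A}): 1.0,
                       frozenset({A, B}): pytest.approx(2 / 3)}
        # {b} is frequent but not closed: {a,b} has equal support

    def test_min_support_one_on_identical_transactions(self):
        db = db_from([{A, B, C}] * 3)
        got = mine_closed_frequent_itemsets(db, 1.0)
        assert got == [(frozenset({A, B, C}), 1.0)]

    def test_support_above_every_item_yields_empty(self):
        db = db_from([{A}, {B}])
        assert mine_closed_frequent_itemsets(db, 0.9) == []

    def test_sorted_by_support_then_size_then_lexicographic(self):
        db = db_from([{A, B}, {A}, {A, B}, {C}])
        got = mine_closed_frequent_itemsets(db, 0.25)
        sups = [s for _, s in got]
        assert sups == sorted(sups, reverse=True)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        db = random_transaction_db(rng, max_items=8, max_transactions=15)
        min_support = float(rng.uniform(0.1, 0.9))
        got = dict(mine_closed_frequent_itemsets(db, min_support))
        expected = brute_force_closed_itemsets(db, min_support)
        assert set(got) == set(expected)
        for s in got:
            assert got[s] == pytest.approx(expected[s])

    def test_length_cap_returns_only_truly_closed_sets(self):
        rng = np.random.default_rng(42)
        db = random_transaction_db(rng, max_items=8, max_transactions=15)
        full = brute_force_closed_itemsets(db, 0.3)
        capped = mine_closed_frequent_itemsets(db, 0.3, max_len=2)
        for s, sup in capped:
            assert s in full and full[s] == pytest.approx(sup)

    @pytest.mark.parametrize("seed", range(5))
    def test_support_anti_monotone(self, seed):
        rng = np.random.default_rng(100 + seed)
        db = random_transaction_db(rng, max_items=6, max_transactions=12)
        mined = mine_closed_frequent_itemsets(db, 0.2)
        sup = dict(mined)
        for s, v in mined:
            for t, w in mined:
                if s < t:
                    assert w <= v + 1e-12


class TestIterativeSearch:
    def test_stops_at_first_support_meeting_budget(self):
        # one very frequent item, many rarer ones
        sets = [{A, B}] * 9 + [{A, C}]
        db = db_from(sets)
        stop, itemsets = iterative_min_support_search(db, max_rules=2,
                                                      init_support=0.95,
                                                      step=0.05, floor=0.05)
        # trajectory: count(s) is non-decreasing as s drops; first s with >= 2 wins
        assert len(itemsets) >= 2
        higher = mine_closed_frequent_itemsets(db, min(stop + 0.05, 1.0))
        assert len(higher) < 2

    def test_max_rules_one_stops_immediately(self):
        db = db_from([{A}] * 10)
        stop, itemsets = iterative_min_support_search(db, 1, 0.9, 0.05, 0.1)
        assert stop == 0.9 and len(itemsets) == 1

    def test_floor_clause_returns_floor_result(self):
        db = db_from([{A}, {B}])
        stop, itemsets = iterative_min_support_search(db, 1000, 0.9, 0.2, 0.3)
        assert stop == pytest.approx(0.3)
        assert dict(itemsets) == dict(mine_closed_frequent_itemsets(db, 0.3))

    def test_terminates_within_bound(self):
        db = db_from([{A}])
        init, step, floor = 0.9, 0.07, 0.1
        stop, _ = iterative_min_support_search(db, 10**6, init, step, floor)
        assert stop >= floor

    @pytest.mark.parametrize("seed", range(5))
    def test_itemset_count_non_increasing_in_support(self, seed):
        rng = np.random.default_rng(seed)
        db = random_transaction_db(rng, max_items=7, max_transactions=15)
        counts = [len(mine_closed_frequent_itemsets(db, s))
                  for s in np.arange(0.9, 0.09, -0.1)]
        assert counts == sorted(counts)


class TestGenerateCars:
    def test_confidence_over_full_training_db(self):
        dbs = {
            "c": db_from([{A, B}, {A}, {A, C}], "c"),
            "d": db_from([{A}], "d"),
        }
        rules = generate_cars([(frozenset({A}), 1.0)], "c", dbs, min_confidence=0.0)
        assert rules[0].confidence == 0.75

    def test_class_exclusive_antecedent_confidence_one(self):
        dbs = {"c": db_from([{A}], "c"), "d": db_from([{B}], "d")}
        rules = generate_cars([(frozenset({A}), 1.0)], "c", dbs, 0.0)
        assert rules[0].confidence == 1.0

    def test_min_confidence_threshold_drops_rule(self):
        dbs = {"c": db_from([{A}] * 3, "c"), "d": db_from([{A}], "d")}
        assert generate_cars([(frozenset({A}), 1.0)], "c", dbs, 0.8) == []


class TestGeneStats:
    def test_class_independent_feature_zero(self):
        dds = tiny_dds()
        # g1 tracks class exactly; craft a third constant feature
        levels = np.hstack([dds.levels, np.ones((6, 1), dtype=np.int8)])
        dds2 = DiscretizedDataset(dds.sample_ids, dds.labels,
                                  dds.feature_uids + ["mRNA:flat"], levels,
                                  np.zeros((3, 2)),
                                  {**dds.omics_of, "mRNA:flat": OmicsType.MRNA})
        st = gene_stats(dds2, tiny_split())
        assert st.infogain["mRNA:flat"] == pytest.approx(0.0)
        assert st.correlation["mRNA:flat"] == 0.0

    def test_perfect_balanced_binary_feature_is_one_bit(self):
        st = gene_stats(tiny_dds(), tiny_split())
        assert st.infogain["mRNA:g1"] == pytest.approx(1.0)
        assert st.correlation["mRNA:g1"] == pytest.approx(1.0)

    def test_independent_feature_near_zero_correlation(self):
        rng = np.random.default_rng(0)
        n = 200
        levels = rng.integers(0, 3, size=(n, 1)).astype(np.int8)
        labels = ["x"] * (n // 2) + ["y"] * (n // 2)
        dds = DiscretizedDataset([f"s{i}" for i in range(n)], labels, ["mRNA:g"],
                                 levels, np.zeros((1, 2)),
                                 {"mRNA:g": OmicsType.MRNA})
        split = SplitSpec([f"s{i}" for i in range(n)], [], 0)
        st = gene_stats(dds, split)
        assert st.correlation["mRNA:g"] < 0.2


class TestScoreCar:
    def _rule(self, conf):
        return ClassAssociationRule(items(("g", 2)), "c", 1.0, conf)

    def _stats(self, ig, corr):
        return GeneStats({"g": ig}, {"g": corr})

    def test_unit_components_score_zero(self):
        r = self._rule(1.0)
        assert score_car(r, self._stats(1.0, 1.0)) == 0.0

    def test_half_components_score_minus_three(self):
        r = self._rule(0.5)
        assert score_car(r, self._stats(0.5, 0.5)) == pytest.approx(-3.0)

    def test_zero_component_gives_minus_inf(self):
        r = self._rule(1.0)
        assert score_car(r, self._stats(1.0, 0.0)) == -math.inf

    def test_rule_stats_are_antecedent_means(self):
        r = ClassAssociationRule(items(("g", 2), ("h", 0)), "c", 1.0, 1.0)
        st = GeneStats({"g": 0.2, "h": 0.6}, {"g": 1.0, "h": 0.5})
        score_car(r, st)
        assert r.info_gain == pytest.approx(0.4)
        assert r.correlation == pytest.approx(0.75)


class TestSelection:
    def _mk(self, ic, sup=0.5, feat="g"):
        r = ClassAssociationRule(items((feat, 1)), "c", sup, 1.0)
        r.information_content = ic
        return r

    def test_top_k_per_class_union(self):
        by_class = {"c": [self._mk(i, feat=f"g{i}") for i in range(5)],
                    "d": [self._mk(i, feat=f"h{i}") for i in range(2)]}
        out = select_top_k(by_class, 3)
        assert len(out) == 5  # 3 from c, both from d

    def test_minus_inf_sorts_last(self):
        good, bad = self._mk(1.0, feat="good"), self._mk(-math.inf, feat="bad")
        out = select_top_k({"c": [bad, good]}, 1)
        assert out == [good]

    def test_equal_scores_tie_break_deterministic(self):
        a = self._mk(1.0, sup=0.5, feat="a")
        b = self._mk(1.0, sup=0.5, feat="b")
        assert select_top_k({"c": [b, a]}, 2) == select_top_k({"c": [a, b]}, 2)
        assert select_top_k({"c": [b, a]}, 1) == [a]  # lexicographic tie-break


class TestSelectedGenes:
    def test_union_of_antecedent_features(self):
        r1 = ClassAssociationRule(items(("g1", 2)), "c1", 1, 1)
        r2 = ClassAssociationRule(items(("g1", 2), ("g2", 0)), "c2", 1, 1)
        assert selected_genes([r1, r2]) == ["g1", "g2"]

    def test_levels_collapse_to_single_node(self):
        r1 = ClassAssociationRule(items(("g1", 2)), "c", 1, 1)
        r2 = ClassAssociationRule(items(("g1", 0)), "c", 1, 1)
        assert selected_genes([r1, r2]) == ["g1"]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            selected_genes([])


def test_rules_round_trip(tmp_path):
    r = ClassAssociationRule(items(("mRNA:g1", 2), ("miRNA:m1", 0)), "c",
                             0.5, 0.75, 0.3, 0.6, -1.5)
    bad = ClassAssociationRule(items(("mRNA:g2", 1)), "d", 0.2, 0.1, 0.0, 0.0,
                               -math.inf)
    save_rules([r, bad], tmp_path / "rules.json")
    loaded = load_rules(tmp_path / "rules.json")
    assert loaded[0] == r
    assert loaded[1].information_content == -math.inf


def test_cba_prune_is_stub():
    with pytest.raises(NotImplementedError):
        cba_prune([], None, None)
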