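"""Enzyme discrimination statistics and indistinguishability networks."""

from itertools import permutations

import networkx as nx
import numpy as np
import pytest

from fid import (combined_stats, enzyme_stats, indistinguishability_graph,
                 profile_key, rank_enzymes)

from conftest import make_toy_db, random_toy_db


def brute_partition(db, enzymes):
    """Group-by oracle: species keyed by their joint fragment multisets."""
    classes = {}
    for r in db.records:
        key = tuple(tuple(sorted(r.profiles[e].fragments)) for e in enzymes)
        classes.setdefault(key, []).append(r.species_label)
    return classes


class TestProfileKey:
    def test_multiset_semantics(self):
        db = make_toy_db({"A": {"E": [100, 200]}, "B": {"E": [200, 100]}})
        a, b = db.records
        assert profile_key(a, ("E",)) == profile_key(b, ("E",))

    def test_fragment_count_matters(self):
        db = make_toy_db({"A": {"E": [100, 200]}, "B": {"E": [100, 200, 1]}})
        a, b = db.records
        assert profile_key(a, ("E",)) != profile_key(b, ("E",))

    def test_order_swapped_tuples_induce_same_partition(self):
        rng = np.random.default_rng(3)
        db = random_toy_db(rng, 20, ["E1", "E2"])
        p12 = {frozenset(v) for v in brute_partition(db, ("E1", "E2")).values()}
        p21 = {frozenset(v) for v in brute_partition(db, ("E2", "E1")).values()}
        assert p12 == p21
        r = db.records[0]
        assert profile_key(r, ("E1", "E2")) != profile_key(r, ("E2", "E1")) or \
            r.profiles["E1"].fragments == r.profiles["E2"].fragments

    def test_missing_enzyme_is_an_error(self, toy_db):
        with pytest.raises(KeyError):
            profile_key(toy_db.records[0], ("nope",))


class TestEnzymeStats:
    def test_toy_counts(self, toy_db):
        s = enzyme_stats(toy_db, "E1")
        assert (s.n_profiles, s.n_identifiable) == (2, 1)

    def test_all_distinct_profiles(self, toy_db):
        s = enzyme_stats(toy_db, "E2")
        assert s.n_identifiable == s.n_species == 3

    def test_matches_brute_force_partition_oracle(self):
        rng = np.random.default_rng(11)
        db = random_toy_db(rng, 40, ["E1", "E2", "E3"])
        for e in ("E1", "E2", "E3"):
            classes = brute_partition(db, (e,))
            s = enzyme_stats(db, e)
            assert s.n_profiles == len(classes)
            assert s.n_identifiable == sum(
                1 for v in classes.values() if len(v) == 1)


class TestCombinedStats:
    def test_separating_pair_identifies_all(self, toy_db):
        s = combined_stats(toy_db, ("E1", "E2"))
        assert s.n_identifiable == 3

    def test_repeated_enzyme_rejected(self, toy_db):
        with pytest.raises(ValueError):
            combined_stats(toy_db, ("E1", "E1"))

    def test_pairwise_monotonicity_on_random_db(self):
        rng = np.random.default_rng(23)
        names = ["E1", "E2", "E3", "E4"]
        db = random_toy_db(rng, 50, names)
        singles = {e: enzyme_stats(db, e).n_identifiable for e in names}
        for pair in permutations(names, 2):
            s = combined_stats(db, pair)
            assert s.n_identifiable >= max(singles[e] for e in pair)
            assert s.n_profiles >= s.n_identifiable
            oracle = brute_partition(db, pair)
            assert s.n_profiles == len(oracle)
            assert s.n_identifiable == sum(
                1 for v in oracle.values() if len(v) == 1)


class TestIndistinguishabilityGraph:
    def test_edge_weight_is_share_percentage(self):
        # A,B identical under 2 of 4 enzymes; each never uniquely identified
        # because X mirrors them elsewhere.
        db = make_toy_db({
            "A": {"E1": [100, 200], "E2": [120, 180], "E3": [300], "E4": [300]},
            "B": {"E1": [100, 200], "E2": [120, 180], "E3": [150, 150], "E4": [130, 170]},
            "X": {"E1": [50, 250], "E2": [50, 250], "E3": [150, 150], "E4": [130, 170]},
            "Y": {"E1": [50, 250], "E2": [50, 250], "E3": [300], "E4": [300]},
        })
        g = indistinguishability_graph(db)
        assert set(g.nodes) == {"A", "B", "X", "Y"}
        assert g.edges["A", "B"]["weight"] == pytest.approx(50.0)

    def test_fully_discriminable_db_gives_empty_graph(self, toy_db):
        g = indistinguishability_graph(toy_db, panel=["E2"])
        assert g.number_of_nodes() == 0

    def test_duplicate_sequences_form_full_weight_clique(self):
        db = make_toy_db(
            {"A": {"E1": [100, 200], "E2": [150, 150]},
             "B": {"E1": [100, 200], "E2": [150, 150]},
             "C": {"E1": [100, 200], "E2": [150, 150]},
             "D": {"E1": [300], "E2": [300]}},
            shared_sequences={"B": "A", "C": "A"})
        g = indistinguishability_graph(db)
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            assert g.edges[a, b]["weight"] == pytest.approx(100.0)

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(31)
        db = random_toy_db(rng, 30, ["E1", "E2", "E3"], n_profiles_pool=3)
        g = indistinguishability_graph(db)
        # union-find over pairs sharing a profile under some enzyme,
        # restricted to never-identifiable species
        never = set(db.species)
        parent = {s: s for s in db.species}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        edges = []
        for e in ("E1", "E2", "E3"):
            groups = {}
            for r in db.records:
                groups.setdefault(tuple(sorted(r.profiles[e].fragments)),
                                  []).append(r.species_label)
            for members in groups.values():
                if len(members) == 1:
                    never.discard(members[0])
                else:
                    edges.extend((a, b) for i, a in enumerate(members)
                                 for b in members[i + 1:])
        for a, b in edges:
            if a in never and b in never:
                parent[find(a)] = find(b)
        expected = {}
        for s in never:
            expected.setdefault(find(s), set()).add(s)
        got = {frozenset(c) for c in nx.connected_components(g)}
        assert got == {frozenset(v) for v in expected.values()}


class TestRankEnzymes:
    def test_expected_order_on_toy_panel(self, toy_db):
        order = [s.enzymes[0] for s in rank_enzymes(toy_db)]
        assert order == ["E2", "E1"]

    def test_ties_break_alphabetically(self):
        db = make_toy_db({
            "A": {"E_b": [100, 200], "E_a": [100, 200]},
            "B": {"E_b": [300], "E_a": [300]},
        })
        order = [s.enzymes[0] for s in rank_enzymes(db)]
        assert order == ["E_a", "E_b"]

    def test_order_consistent_with_recomputed_stats(self):
        rng = np.random.default_rng(41)
        db = random_toy_db(rng, 30, ["E1", "E2", "E3", "E4"])
        table = rank_enzymes(db)
        keys = [(-s.n_identifiable, -s.n_profiles, s.enzymes[0]) for s in table]
        assert keys == sorted(keys)
        for s in table:
            assert s == enzyme_stats(db, s.enzymes[0])
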