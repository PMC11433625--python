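"""Profile matching, progressive identification and the combination search."""

from itertools import permutations

import numpy as np
import pytest

from fid import (CalibrationModel, ComboSearchConfig, MeasuredProfile,
                 enzyme_frequency, evaluate_identification, identify_species,
                 match_profile, search_combinations)
from fid.identify import ComboRow, ComboResult
from fid.restriction import FragmentProfile
from fid.size_error import permissive_range

from conftest import make_toy_db, random_toy_db


def frag_profile(enzyme, fragments):
    return FragmentProfile(enzyme=enzyme, fragments=tuple(fragments),
                           amplicon_length=sum(fragments))


@pytest.fixture
def loose_model():
    """A tolerant gel model: +/- a few percent of the size."""
    return CalibrationModel(kind="varpow", beta0=0.0, beta1=1.0, sigma=1.0,
                            delta=0.5, min_detectable=0.0)


class TestMatchProfile:
    def test_identity_scores_all_fragments(self, exact_model):
        ref = frag_profile("E", [320, 230, 180])
        q = MeasuredProfile("E", (320, 230, 180))
        assert match_profile(q, ref, exact_model) == 3

    def test_disjoint_profiles_score_zero(self, exact_model):
        ref = frag_profile("E", [1000, 2000])
        q = MeasuredProfile("E", (10, 20))
        assert match_profile(q, ref, exact_model) == 0

    def test_equals_exhaustive_assignment_oracle(self, loose_model):
        rng = np.random.default_rng(4)
        for _ in range(60):
            nq, nr = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            qf = tuple(float(v) for v in rng.uniform(100, 900, nq))
            rf = [int(v) for v in rng.uniform(100, 900, nr)]
            ref = FragmentProfile(enzyme="E", fragments=tuple(rf),
                                  amplicon_length=sum(rf))
            q = MeasuredProfile("E", qf)
            got = match_profile(q, ref, loose_model)
            # oracle: enumerate every one-to-one assignment of a query
            # subset onto a reference subset
            from itertools import combinations

            ranges = [permissive_range(loose_model, x) for x in q.fragments]
            best = 0
            k = min(nq, nr)
            for qs in combinations(range(nq), k):
                for subset in permutations(range(nr), k):
                    score = sum(
                        ranges[i][0] <= ref.fragments[j] <= ranges[i][1]
                        for i, j in zip(qs, subset))
                    best = max(best, score)
            assert got == best

    def test_containment_mode_counts_compatible_queries(self, exact_model):
        ref = frag_profile("E", [300, 300])
        q = MeasuredProfile("E", (300.0, 300.0, 300.0))
        assert match_profile(q, ref, exact_model) == 2          # one-to-one
        assert match_profile(q, ref, exact_model,
                             score_mode="containment") == 3     # many-to-one

    def test_reference_penalty_mode(self, exact_model):
        ref = frag_profile("E", [300, 200, 100])
        q = MeasuredProfile("E", (300.0,))
        assert match_profile(q, ref, exact_model) == 1
        assert match_profile(q, ref, exact_model, reference_penalty=0.5) == 0.0

    def test_sub_detectable_fragments_ignored(self):
        m = CalibrationModel(kind="lm", beta0=0, beta1=1, sigma=0,
                             min_detectable=100)
        ref = frag_profile("E", [350, 90, 60])
        q = MeasuredProfile("E", (350.0, 90.0))
        assert match_profile(q, ref, m) == 1


class TestIdentifySpecies:
    def test_noiseless_self_query_recovers_species(self, toy_db, exact_model):
        for rec in toy_db.records:
            queries = [MeasuredProfile(e, rec.profiles[e].fragments)
                       for e in ("E1", "E2")]
            res = identify_species(toy_db, rec.amplicon.length, queries,
                                   exact_model, truth=rec.species_label)
            assert res.identified
            assert rec.species_label in res.final_candidates

    def test_candidate_sets_shrink_monotonically(self, exact_model):
        rng = np.random.default_rng(8)
        db = random_toy_db(rng, 30, ["E1", "E2"], amplicon_length=600)
        rec = db.records[0]
        one = identify_species(db, 600, [MeasuredProfile(
            "E1", rec.profiles["E1"].fragments)], exact_model)
        two = identify_species(db, 600, [
            MeasuredProfile("E1", rec.profiles["E1"].fragments),
            MeasuredProfile("E2", rec.profiles["E2"].fragments)], exact_model)
        assert two.final_candidates <= one.final_candidates
        sizes = [len(s.candidates) for s in two.stages]
        assert sizes == sorted(sizes, reverse=True)

    def test_unknown_query_enzyme_is_an_error(self, toy_db, exact_model):
        with pytest.raises(KeyError):
            identify_species(toy_db, 300,
                             [MeasuredProfile("nope", (100.0,))], exact_model)

    def test_empty_amplicon_stage_yields_no_identification(self, toy_db,
                                                           exact_model):
        res = identify_species(toy_db, 5000.0, [], exact_model, truth="A")
        assert res.final_candidates == set()
        assert res.identified is False
        assert res.precision is None

    def test_stage_trace_records_scores(self, toy_db, exact_model):
        rec = toy_db.record("C")
        res = identify_species(
            toy_db, rec.amplicon.length,
            [MeasuredProfile("E1", rec.profiles["E1"].fragments)], exact_model)
        assert res.stages[0].name == "amplicon_length"
        assert res.stages[1].name == "E1"
        assert set(res.stages[1].scores) >= res.final_candidates


class TestEvaluateIdentification:
    def test_counting(self, toy_db, exact_model):
        queries = []
        for rec in toy_db.records:
            queries.append((rec.species_label, float(rec.amplicon.length),
                            [MeasuredProfile("E2", rec.profiles["E2"].fragments)]))
        # one deliberately wrong truth label
        queries.append(("A", float(toy_db.record("C").amplicon.length),
                        [MeasuredProfile("E2",
                                         toy_db.record("C").profiles["E2"].fragments)]))
        report = evaluate_identification(toy_db, queries, exact_model)
        assert report.pct_identified == pytest.approx(75.0)
        assert report.precision_median == 0

    def test_precision_is_coselected_count(self, exact_model):
        db = make_toy_db({
            "truth": {"E": [100, 200]},
            "X": {"E": [100, 200]},
            "Y": {"E": [100, 200]},
        })
        res = identify_species(db, 300, [MeasuredProfile("E", (100.0, 200.0))],
                               exact_model, truth="truth")
        assert res.identified and res.precision == 2

    def test_aggregates_equal_recomputation_from_table(self, exact_model):
        rng = np.random.default_rng(19)
        db = random_toy_db(rng, 25, ["E1", "E2"], amplicon_length=500)
        queries = [(r.species_label, 500.0,
                    [MeasuredProfile("E1", r.profiles["E1"].fragments)])
                   for r in db.records]
        report = evaluate_identification(db, queries, exact_model)
        df = report.per_query
        assert report.pct_identified == pytest.approx(
            100.0 * df["identified"].mean())
        precs = df.loc[df["precision"].notna(), "precision"]
        assert report.precision_median == precs.median()


class TestSearchCombinations:
    def _shatter_db(self):
        # E1 splits {A,B,C,D} into {A,B} vs {C,D}; E2 splits within pairs.
        return make_toy_db({
            "A": {"E1": [100, 300], "E2": [150, 250], "E3": [400]},
            "B": {"E1": [100, 300], "E2": [180, 220], "E3": [400]},
            "C": {"E1": [200, 200], "E2": [150, 250], "E3": [400]},
            "D": {"E1": [200, 200], "E2": [180, 220], "E3": [400]},
        })

    def test_shattering_pair_is_fully_precise(self, exact_model):
        db = self._shatter_db()
        cfg = ComboSearchConfig(n_query_species=4, seed=0,
                                max_coselected_single=50)
        res = search_combinations(db, exact_model, k_range=(2,), config=cfg)
        best = res.rows[0]
        assert set(best.enzymes) == {"E1", "E2"}
        assert best.pct_identified == 100.0
        assert best.n_precise == res.n_queries

    def test_both_orders_enumerated(self, exact_model):
        db = self._shatter_db()
        cfg = ComboSearchConfig(n_query_species=4, seed=0)
        res = search_combinations(db, exact_model, k_range=(2,), config=cfg,
                                  exhaustive=True)
        combos = {r.enzymes for r in res.rows}
        assert ("E1", "E2") in combos and ("E2", "E1") in combos

    def test_pruned_results_subset_of_exhaustive(self, exact_model):
        rng = np.random.default_rng(77)
        db = random_toy_db(rng, 20, [f"E{i}" for i in range(1, 9)],
                           amplicon_length=700, n_profiles_pool=5)
        cfg = ComboSearchConfig(n_query_species=20, seed=1,
                                max_coselected_single=50,
                                first_stage_panel_size=5,
                                later_stage_panel_size=5)
        pruned = search_combinations(db, exact_model, k_range=(2, 3),
                                     config=cfg)
        full = search_combinations(db, exact_model, k_range=(2, 3), config=cfg,
                                   exhaustive=True)
        full_by_combo = {r.enzymes: r for r in full.rows}
        assert pruned.rows, pruned.reason
        for row in pruned.rows:
            assert row == full_by_combo[row.enzymes]

    def test_empty_pruned_space_reports_reason(self, exact_model):
        # single amplicon length and identical profiles: nothing identifies
        db = make_toy_db({
            "A": {"E1": [100, 200]},
            "B": {"E1": [100, 200]},
            "C": {"E1": [100, 200]},
        })
        cfg = ComboSearchConfig(n_query_species=3, seed=0)
        res = search_combinations(db, exact_model, k_range=(2,), config=cfg)
        assert res.rows == [] and res.reason

    def test_combination_benefit_is_monotone_in_k(self, exact_model):
        """Adding profiles tends to reduce the co-selected species count."""
        rng = np.random.default_rng(55)
        db = random_toy_db(rng, 30, [f"E{i}" for i in range(1, 6)],
                           amplicon_length=800, n_profiles_pool=4)
        cfg = ComboSearchConfig(n_query_species=30, seed=3)
        res = search_combinations(db, exact_model, k_range=(2, 3), config=cfg,
                                  exhaustive=True)
        med = {}
        for k in (2, 3):
            vals = [r.median_coselected for r in res.rows
                    if len(r.enzymes) == k and r.median_coselected is not None]
            med[k] = np.median(vals)
        assert med[3] <= med[2]


class TestEnzymeFrequency:
    def test_shared_enzyme_at_full_frequency(self):
        rows = [ComboRow(("AluI", "BfaI", "Cac8I"), 100.0, 0, 2),
                ComboRow(("AluI", "TaqI", "MseI"), 100.0, 0, 1)]
        freq = enzyme_frequency(rows, precise_only=True)
        assert freq["AluI"] == pytest.approx(100.0)
        assert freq["BfaI"] == pytest.approx(50.0)

    def test_absent_from_precise_set(self):
        rows = [ComboRow(("AluI", "BfaI"), 100.0, 0, 2),
                ComboRow(("TaqI", "MseI"), 50.0, 3, 0)]
        freq = enzyme_frequency(rows, precise_only=True)
        assert "TaqI" not in freq

    def test_matches_recount_oracle_and_sums_to_k(self):
        rng = np.random.default_rng(6)
        names = ["A", "B", "C", "D", "E"]
        rows = []
        for _ in range(40):
            combo = tuple(np.array(names)[rng.choice(5, 3, replace=False)])
            rows.append(ComboRow(combo, 100.0, 1, int(rng.integers(0, 3))))
        freq = enzyme_frequency(rows, precise_only=False)
        counts = {}
        for r in rows:
            for e in r.enzymes:
                counts[e] = counts.get(e, 0) + 1
        for e, pct in freq.items():
            assert pct == pytest.approx(100.0 * counts[e] / len(rows))
        assert sum(freq.values()) == pytest.approx(300.0)
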