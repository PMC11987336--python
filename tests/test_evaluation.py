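import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from rxnsearch.evaluation import (
    FeedbackTrajectory,
    MetricsReport,
    ScenarioSpec,
    halogen_set,
    max_tanimoto,
    metrics_from_ranks,
    product_prediction_metrics,
    ranks_from_embeddings,
    rate_by_scenario,
    simulate_feedback_loop,
)
from rxnsearch.featurization import featurize_record
from rxnsearch.feedback import FeedbackConfig
from rxnsearch.pca_compress import fit_basis, stack_embeddings
from rxnsearch.reaction_io import ReactionRecord
from rxnsearch.search import QuerySpec, build_index


class TestMetricsFromRanks:
    def test_all_rank_one(self):
        report = metrics_from_ranks([1, 1, 1])
        assert report.mrr == 1.0 and report.mr == 1.0
        assert all(v == 1.0 for v in report.hit_at.values())

    def test_hand_case_ranks_1_and_4(self):
        report = metrics_from_ranks([1, 4])
        assert report.mrr == pytest.approx(0.625)
        assert report.mr == pytest.approx(2.5)
        assert report.hit_at[3] == pytest.approx(0.5)
        assert report.hit_at[5] == 1.0

    def test_hit_monotone_and_bounds(self, rng):
        ranks = rng.integers(1, 50, size=100)
        report = metrics_from_ranks(ranks)
        ks = sorted(report.hit_at)
        assert all(report.hit_at[a] <= report.hit_at[b] for a, b in zip(ks, ks[1:]))
        assert report.hit_at[1] <= report.mrr <= 1.0

    def test_uniform_null_mean_rank(self, rng):
        c = 40
        queries = rng.normal(size=(300, 8))
        candidates = rng.normal(size=(c, 8))
        truth = rng.integers(0, c, size=300)
        ranks = ranks_from_embeddings(queries, candidates, truth)
        expected = (c + 1) / 2
        assert np.mean(ranks) == pytest.approx(expected, rel=0.15)

    def test_ranks_against_sort_oracle(self, rng):
        queries = rng.normal(size=(10, 4))
        candidates = rng.normal(size=(20, 4))
        truth = rng.integers(0, 20, size=10)
        ranks = ranks_from_embeddings(queries, candidates, truth)
        for i in range(10):
            d = np.linalg.norm(candidates - queries[i], axis=1)
            assert ranks[i] == int((d < d[truth[i]]).sum()) + 1


class TestProductPredictionMetrics:
    def test_pool_and_truth_validation(self, tiny_model):
        records = [ReactionRecord(record_id="a", product="CC", reactants=["CCBr"])]
        with pytest.raises(ValueError, match="missing"):
            product_prediction_metrics(tiny_model, records, candidate_pool=["CCC"])

    def test_matches_manual_route(self, tiny_model, small_records):
        subset = small_records[:15]
        report = product_prediction_metrics(tiny_model, subset)
        pool = list(dict.fromkeys(r.product for r in subset))
        pool_z = np.stack(
            [
                tiny_model.embed_record(
                    featurize_record(
                        ReactionRecord(record_id="p", product=s, reactants=[s])
                    )
                ).z
                for s in pool
            ]
        )
        zhat = np.stack(
            [tiny_model.embed_record(featurize_record(r)).z_hat for r in subset]
        )
        truth = np.array([pool.index(r.product) for r in subset])
        manual = metrics_from_ranks(ranks_from_embeddings(zhat, pool_z, truth))
        assert report.mr == manual.mr
        assert report.mrr == manual.mrr


class TestHalogensAndTanimoto:
    def test_halogen_sets(self):
        assert halogen_set("CCCl") == {"Cl"}
        assert halogen_set("CC") == frozenset()
        assert halogen_set("FC(Br)I") == {"F", "Br", "I"}

    def test_tanimoto_identical_is_one(self):
        assert max_tanimoto("CCO", ["CCO"]) == 1.0

    def test_tanimoto_disjoint_is_low(self):
        assert max_tanimoto("CCCCCCCC", ["[Na+]"]) == 0.0

    def test_tanimoto_requires_reactants(self):
        with pytest.raises(ValueError):
            max_tanimoto("CC", [])

    def test_matches_toolkit_oracle(self):
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        product, reactants = "CCOC(C)=O", ["CCO", "CC(=O)O", "c1ccccc1"]
        fp_p = gen.GetFingerprint(Chem.MolFromSmiles(product))
        expected = max(
            DataStructs.TanimotoSimilarity(fp_p, gen.GetFingerprint(Chem.MolFromSmiles(r)))
            for r in reactants
        )
        assert max_tanimoto(product, reactants) == pytest.approx(expected, abs=1e-12)


class TestScenarios:
    def _hit(self, product, reactants):
        return ReactionRecord(record_id="h", product=product, reactants=reactants)

    def test_scenario1_set_semantics(self):
        scenario = ScenarioSpec(scenario_id=1)
        query = QuerySpec(product="CCCl")
        assert rate_by_scenario(query, self._hit("CCCCl", ["CC"]), scenario) == 1
        assert rate_by_scenario(query, self._hit("ClCCBr", ["CC"]), scenario) == -1
        # empty == empty counts as a match
        query2 = QuerySpec(product="CCO")
        assert rate_by_scenario(query2, self._hit("CCC", ["CC"]), scenario) == 1

    def test_scenario1_multiset_variant(self):
        scenario = ScenarioSpec(scenario_id=1, halogen_multiset=True)
        query = QuerySpec(product="ClCCCl")
        assert rate_by_scenario(query, self._hit("ClCC(C)Cl", ["CC"]), scenario) == 1
        assert rate_by_scenario(query, self._hit("CCCl", ["CC"]), scenario) == -1
        # set semantics would call this a match
        assert rate_by_scenario(
            query, self._hit("CCCl", ["CC"]), ScenarioSpec(scenario_id=1)
        ) == 1

    def test_scenario2_default_two(self):
        scenario = ScenarioSpec(scenario_id=2)
        query = QuerySpec(product="CCO")  # no reactants specified
        assert rate_by_scenario(query, self._hit("CC", ["CCO", "CCBr"]), scenario) == 1
        assert rate_by_scenario(query, self._hit("CC", ["CCO"]), scenario) == -1

    def test_scenario2_matches_query_count(self):
        scenario = ScenarioSpec(scenario_id=2)
        query = QuerySpec(product="CCO", reactants=["CC", "CCC", "CCCC"])
        assert rate_by_scenario(query, self._hit("CC", ["C", "CC", "CCC"]), scenario) == 1

    def test_scenario3_self_similarity(self):
        scenario = ScenarioSpec(scenario_id=3)
        query = QuerySpec(product="CCO")
        assert rate_by_scenario(query, self._hit("CCCCCC", ["CCCCCC", "O"]), scenario) == 1
        assert rate_by_scenario(query, self._hit("CCCCCC", ["[Na+]"]), scenario) == -1

    def test_scenarios_4_and_5_conjunctions(self):
        query = QuerySpec(product="CCCl")
        hit_both = self._hit("ClCCCCCC", ["ClCCCCCC", "O"])
        assert rate_by_scenario(query, hit_both, ScenarioSpec(scenario_id=5)) == 1
        hit_halogen_only = self._hit("ClCCCCCC", ["[Na+]"])
        assert rate_by_scenario(query, hit_halogen_only, ScenarioSpec(scenario_id=5)) == -1
        hit_two = self._hit("ClCC", ["CC", "CCC"])
        assert rate_by_scenario(query, hit_two, ScenarioSpec(scenario_id=4)) == 1
        hit_one = self._hit("ClCC", ["CC"])
        assert rate_by_scenario(query, hit_one, ScenarioSpec(scenario_id=4)) == -1

    def test_rater_is_pure(self):
        scenario = ScenarioSpec(scenario_id=3)
        query = QuerySpec(product="CCO")
        hit = self._hit("CCCCCC", ["CCCCCC"])
        assert all(
            rate_by_scenario(query, hit, scenario) == rate_by_scenario(query, hit, scenario)
            for _ in range(3)
        )

    def test_invalid_scenario_id(self):
        with pytest.raises(ValueError):
            ScenarioSpec(scenario_id=6)


def _tiny_db(records, model):
    pairs = [model.embed_record(featurize_record(r)) for r in records]
    basis = fit_basis(stack_embeddings(pairs), evr_threshold=0.99)
    return build_index(records, model, basis), basis


class TestSimulateFeedbackLoop:
    def _records(self, n_reactants):
        cores = ["CC", "CCC", "CCCC", "CCO", "CCN(C)C", "c1ccccc1", "CCCCCC", "C1CCCCC1"]
        records = []
        for i, core in enumerate(cores):
            reactants = [f"Cl{c}" for c in cores[:n_reactants - 1]] + [f"O{core}"]
            records.append(
                ReactionRecord(
                    record_id=f"s{i}", product=f"O(C){core}", reactants=reactants
                )
            )
        return records

    def test_ceiling_case_all_positive(self, tiny_model):
        records = self._records(2)  # every record has exactly 2 reactants
        db, basis = _tiny_db(records, tiny_model)
        queries = [QuerySpec(product=records[0].product, K=4)]
        trajectory = simulate_feedback_loop(
            queries, db, tiny_model, basis, ScenarioSpec(scenario_id=2), records,
            K=4, n_updates=1,
            config=FeedbackConfig(iterations=2, minibatch_size=4, seed=0),
        )
        assert trajectory.hit_ratios == [1.0, 1.0]

    def test_floor_case_all_negative(self, tiny_model):
        records = self._records(3)  # all 3 reactants, target is 2
        db, basis = _tiny_db(records, tiny_model)
        queries = [QuerySpec(product=records[0].product, K=4)]
        trajectory = simulate_feedback_loop(
            queries, db, tiny_model, basis, ScenarioSpec(scenario_id=2), records,
            K=4, n_updates=1,
            config=FeedbackConfig(iterations=2, minibatch_size=4, seed=0),
        )
        assert trajectory.hit_ratios == [0.0, 0.0]

    def test_round_zero_independent_of_config(self, tiny_model, small_records):
        db, basis = _tiny_db(small_records[:30], tiny_model)
        queries = [QuerySpec(product=small_records[0].product, K=5)]
        r0 = []
        for iterations in (1, 5):
            trajectory = simulate_feedback_loop(
                queries, db, tiny_model, basis, ScenarioSpec(scenario_id=2),
                small_records[:30], K=5, n_updates=1,
                config=FeedbackConfig(iterations=iterations, minibatch_size=8, seed=0),
            )
            r0.append(trajectory.hit_ratios[0])
        assert r0[0] == r0[1]

    def test_trajectory_length(self, tiny_model, small_records):
        db, basis = _tiny_db(small_records[:20], tiny_model)
        queries = [QuerySpec(product=small_records[0].product, K=3)]
        trajectory = simulate_feedback_loop(
            queries, db, tiny_model, basis, ScenarioSpec(scenario_id=2),
            small_records[:20], K=3, n_updates=2,
            config=FeedbackConfig(iterations=1, minibatch_size=8, seed=0),
        )
        assert trajectory.rounds == 2
        assert len(trajectory.hit_ratios) == 3
        assert all(0.0 <= v <= 1.0 for v in trajectory.hit_ratios)

    def test_empty_queries_rejected(self, tiny_model, small_records):
        db, basis = _tiny_db(small_records[:10], tiny_model)
        with pytest.raises(ValueError):
            simulate_feedback_loop(
                [], db, tiny_model, basis, ScenarioSpec(scenario_id=2), small_records[:10]
            )
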