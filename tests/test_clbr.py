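import itertools

import numpy as np
import pytest

from ebca.agreement import adjusted_rand_index
from ebca.clbr import (Dendrogram, Element, MixedDissimilarityParams, Schema,
                       build_prototype, calinski_cut, clbr_cluster,
                       cut_dendrogram, mixed_distance, pairwise_sq_distance,
                       rnn_ward_cluster)
from ebca.rules import parse_rules
from ebca.synth import default_patient_config, generate_patients

from oracles import greedy_ward_oracle

NUM_SCHEMA = Schema(numeric=("x",), categorical=(), categories={})
MIX_SCHEMA = Schema(numeric=("x",), categorical=("c",),
                    categories={"c": ("red", "blue")})


def num_el(v, rid=0, schema=NUM_SCHEMA):
    return Element.from_record(schema, rid, {"x": float(v)})


class TestMixedDistance:
    def test_identical_records_distance_zero(self):
        a = Element.from_record(MIX_SCHEMA, 0, {"x": 1.0, "c": "red"})
        b = Element.from_record(MIX_SCHEMA, 1, {"x": 1.0, "c": "red"})
        params = MixedDissimilarityParams.unscaled(1, 1)
        assert mixed_distance(a, b, params) == 0.0

    def test_pure_numeric_reduces_to_normalised_euclidean(self):
        params = MixedDissimilarityParams(1.0, 0.0, np.array([2.0]))
        a, b = num_el(0.0), num_el(4.0, 1)
        assert mixed_distance(a, b, params) == pytest.approx((4.0 / 2.0) ** 2)

    def test_hand_computed_mixed_example(self):
        params = MixedDissimilarityParams(0.5, 0.5, np.array([1.0]))
        a = Element.from_record(MIX_SCHEMA, 0, {"x": 0.0, "c": "red"})
        b = Element.from_record(MIX_SCHEMA, 1, {"x": 1.0, "c": "blue"})
        assert mixed_distance(a, b, params) == pytest.approx(1.0)

    def test_half_l1_between_frequency_distributions(self):
        params = MixedDissimilarityParams(0.0, 1.0, np.array([1.0]))
        a = build_prototype(MIX_SCHEMA, [(0, {"x": 0.0, "c": "red"}),
                                         (1, {"x": 0.0, "c": "red"}),
                                         (2, {"x": 0.0, "c": "blue"})])
        b = Element.from_record(MIX_SCHEMA, 3, {"x": 0.0, "c": "blue"})
        # freq a = (2/3, 1/3), b = (0, 1); half L1 = 2/3
        assert mixed_distance(a, b, params) == pytest.approx(2.0 / 3.0)

    def test_missing_renormalisation(self):
        schema = Schema(numeric=("x", "y"), categorical=(), categories={})
        params = MixedDissimilarityParams(1.0, 0.0, np.array([1.0, 1.0]))
        a = Element.from_record(schema, 0, {"x": 0.0, "y": None})
        b = Element.from_record(schema, 1, {"x": 3.0, "y": 5.0})
        # only x comparable: mean over 1 variable
        assert mixed_distance(a, b, params) == pytest.approx(9.0)

    def test_no_comparable_variable_errors(self):
        schema = Schema(numeric=("x",), categorical=(), categories={})
        params = MixedDissimilarityParams(1.0, 0.0, np.array([1.0]))
        a = Element.from_record(schema, 0, {"x": None})
        b = Element.from_record(schema, 1, {"x": 1.0})
        with pytest.raises(ValueError, match="comparable"):
            mixed_distance(a, b, params)

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_axiom_spot_checks(self, seed, mixed_table_factory):
        rng = np.random.default_rng(seed)
        table = mixed_table_factory(rng, 6, n_num=2, n_cat=1)
        schema = Schema.from_table(table)
        params = MixedDissimilarityParams.from_table(table)
        els = [Element.from_record(schema, rid, rec) for rid, rec in table.records()]
        D = pairwise_sq_distance(els, params)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        # triangle inequality on the (unsquared) numeric-only distance
        params_num = MixedDissimilarityParams(1.0, 0.0, params.scales)
        Dn = np.sqrt(pairwise_sq_distance(els, params_num))
        for i, j, k in itertools.combinations(range(6), 3):
            assert Dn[i, j] <= Dn[i, k] + Dn[k, j] + 1e-9


class TestPrototype:
    def test_singleton_prototype_is_the_record(self):
        proto = build_prototype(MIX_SCHEMA, [(7, {"x": 2.0, "c": "red"})])
        assert proto.mass == 1
        assert proto.numeric_means()[0] == 2.0
        assert proto.category_frequencies(0) == pytest.approx([1.0, 0.0])

    def test_numeric_mean(self):
        proto = build_prototype(NUM_SCHEMA, [(0, {"x": 2.0}), (1, {"x": 4.0})])
        assert proto.numeric_means()[0] == 3.0
        assert proto.mass == 2

    def test_category_frequencies_count(self):
        recs = [(i, {"x": 0.0, "c": c}) for i, c in enumerate(["red", "red", "blue"])]
        proto = build_prototype(MIX_SCHEMA, recs)
        assert proto.category_frequencies(0) == pytest.approx([2 / 3, 1 / 3])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            build_prototype(NUM_SCHEMA, [])

    def test_missing_aware_mean(self):
        proto = build_prototype(NUM_SCHEMA, [(0, {"x": 2.0}), (1, {"x": None})])
        assert proto.numeric_means()[0] == 2.0
        assert proto.mass == 2


class TestRNNWard:
    def test_worked_1d_example(self):
        params = MixedDissimilarityParams.unscaled(1)
        els = [num_el(v, i) for i, v in enumerate([0, 1, 10, 11])]
        d = rnn_ward_cluster(els, params)
        assert d.merges[0] == (0, 1, pytest.approx(0.5))
        assert d.merges[1] == (2, 3, pytest.approx(0.5))
        assert d.merges[2][2] == pytest.approx(100.0)

    def test_identical_leaves_merge_at_zero(self):
        params = MixedDissimilarityParams.unscaled(1)
        d = rnn_ward_cluster([num_el(5, 0), num_el(5, 1), num_el(9, 2)], params)
        assert d.merges[0] == (0, 1, pytest.approx(0.0))

    def test_merge_count_and_nondecreasing_heights(self):
        rng = np.random.default_rng(2)
        params = MixedDissimilarityParams.unscaled(1)
        els = [num_el(v, i) for i, v in enumerate(rng.normal(size=15))]
        d = rnn_ward_cluster(els, params)
        heights = d.heights()
        assert len(d.merges) == 14
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_fewer_than_two_leaves_rejected(self):
        with pytest.raises(ValueError):
            rnn_ward_cluster([num_el(1)], MixedDissimilarityParams.unscaled(1))

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_small_mixed(self, seed, mixed_table_factory):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        table = mixed_table_factory(rng, n, n_num=2, n_cat=1,
                                    missing_rate=0.1 if seed % 2 else 0.0)
        schema = Schema.from_table(table)
        params = MixedDissimilarityParams.from_table(table)
        els = [Element.from_record(schema, rid, rec) for rid, rec in table.records()]
        result = rnn_ward_cluster(els, params).canonical_merges()
        expected = greedy_ward_oracle(els, params)
        assert len(result) == len(expected)
        for (la, ra, ha), (lb, rb, hb) in zip(result, expected):
            assert {la, ra} == {lb, rb}
            assert ha == pytest.approx(hb, abs=1e-9)

    def test_mass_weighted_prototype_attracts_like_its_members(self):
        # a mass-40 prototype at 0 vs unit points: first merge cost scales with mass
        params = MixedDissimilarityParams.unscaled(1)
        heavy = build_prototype(NUM_SCHEMA, [(i, {"x": 0.0}) for i in range(40)])
        light = num_el(1.0, 100)
        d2 = mixed_distance(heavy, light, params)
        cost = heavy.mass * light.mass / (heavy.mass + light.mass) * d2
        assert cost == pytest.approx(40 / 41)


class TestCalinski:
    def test_zero_within_scatter_sentinel(self):
        params = MixedDissimilarityParams.unscaled(1)
        els = [num_el(v, i) for i, v in enumerate([0, 0, 10, 10])]
        d = rnn_ward_cluster(els, params)
        curve = calinski_cut(d, els, params, kmax=3)
        assert curve.values[2] == float("inf")
        assert curve.k_star == 2

    def test_hand_computed_ch_equals_50(self):
        params = MixedDissimilarityParams.unscaled(1)
        els = [num_el(v, i) for i, v in enumerate([0, 2, 10, 12])]
        d = rnn_ward_cluster(els, params)
        curve = calinski_cut(d, els, params, kmax=3)
        assert curve.values[2] == pytest.approx(50.0)
        assert curve.k_star == 2

    def test_kmax_out_of_range(self):
        params = MixedDissimilarityParams.unscaled(1)
        els = [num_el(v, i) for i, v in enumerate([0, 2, 10])]
        d = rnn_ward_cluster(els, params)
        with pytest.raises(ValueError):
            calinski_cut(d, els, params, kmax=5)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_three_clusters_recovered(self, seed):
        table, _ = generate_patients(default_patient_config(n=150), seed=seed)
        kb = parse_rules("")
        _, partition, curve, _ = clbr_cluster(table, kb)
        assert curve.k_star == 3

    def test_cut_labels_partition_all_leaves(self):
        rng = np.random.default_rng(1)
        params = MixedDissimilarityParams.unscaled(1)
        els = [num_el(v, i) for i, v in enumerate(rng.normal(size=12))]
        d = rnn_ward_cluster(els, params)
        for k in range(1, 12):
            labels = cut_dendrogram(d, k)
            assert len(labels) == 12
            assert len(set(labels)) == k


class TestClbrPipeline:
    def test_empty_kb_reduces_to_plain_ward(self):
        table, _ = generate_patients(default_patient_config(n=60), seed=4)
        kb = parse_rules("")
        _, partition, curve, _ = clbr_cluster(table, kb)
        schema = Schema.from_table(table)
        params = MixedDissimilarityParams.from_table(table)
        els = [Element.from_record(schema, rid, rec) for rid, rec in table.records()]
        dendro = rnn_ward_cluster(els, params)
        plain = cut_dendrogram(dendro, curve.k_star)
        ids = table.unit_ids
        ari = adjusted_rand_index([partition.labels[i] for i in ids], plain)
        assert ari == pytest.approx(1.0)

    def test_rule_class_lands_intact(self, case_meta):
        table, _ = generate_patients(default_patient_config(n=120), seed=8)
        kb = parse_rules(
            "r1: if (GAFCLA < 40) and (MAXECFOS_B = Every_Day) then severe",
            case_meta)
        _, partition, _, rule_partition = clbr_cluster(table, kb)
        members = [rid for rid, g in rule_partition.assignments.items() if g == "r1"]
        assert len(members) > 1
        labels = {partition.labels[rid] for rid in members}
        assert len(labels) == 1
        cls = labels.pop()
        assert partition.provenance[cls] == "rule-seeded"

    def test_rule_capturing_planted_cluster_preserves_solution(self, case_meta):
        config = default_patient_config(n=120)
        table, truth = generate_patients(config, seed=2)
        ids = table.unit_ids
        kb0 = parse_rules("")
        _, p0, _, _ = clbr_cluster(table, kb0)
        kb1 = parse_rules(
            "r1: if ((GAFCLA < 40) or (GAFSOCIAL < 40)) and "
            "((MAXECFOS_A > 15) and (MAXECFOS_B = Every_Day)) then severely-ill",
            case_meta)
        _, p1, _, _ = clbr_cluster(table, kb1)
        ari0 = adjusted_rand_index([truth[i] for i in ids],
                                   [p0.labels[i] for i in ids])
        ari1 = adjusted_rand_index([truth[i] for i in ids],
                                   [p1.labels[i] for i in ids])
        assert ari1 >= ari0 - 1e-9

    def test_rule_with_no_members_is_skipped(self, case_meta):
        table, _ = generate_patients(default_patient_config(n=40), seed=3)
        kb = parse_rules("r1: if GAFCLA > 500 then impossible", case_meta)
        _, partition, _, rule_partition = clbr_cluster(table, kb)
        assert rule_partition.counts["r1"] == 0
        assert partition.k >= 2

    def test_semantic_preservation_random_kbs(self, case_meta):
        rng = np.random.default_rng(0)
        for seed in range(5):
            table, _ = generate_patients(
                default_patient_config(n=50), seed=seed)
            thresh = float(rng.integers(35, 75))
            kb = parse_rules(f"r1: if GAFCLA < {thresh} then low", case_meta)
            _, partition, _, rp = clbr_cluster(table, kb)
            members = [rid for rid, g in rp.assignments.items() if g == "r1"]
            if members:
                assert len({partition.labels[m] for m in members}) == 1
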