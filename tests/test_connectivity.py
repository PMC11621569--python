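"""Thresholded connectivity: aggregation, laterality, profiles, tracing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clocknet.connectivity import (
    Thresholds,
    aggregate_edges,
    build_profiles,
    cluster_profiles,
    cosine_similarity,
    disynaptic_connections,
    fan_in_estimate,
    input_share,
    laterality_split,
    pair_counts,
    summarize_disynaptic,
    superclass_breakdown,
    top_partners,
)

from .conftest import make_annotations, make_synapses, random_synapse_table


def brute_force_disynaptic(sources, targets, synapses, threshold):
    """Independent O(n^3) oracle over all (source, mid, target) triples."""
    counts = {}
    for r in synapses.itertuples(index=False):
        key = (r.pre_id, r.post_id)
        counts[key] = counts.get(key, 0) + int(r.n_synapses)
    mids = sorted({i for pair in counts for i in pair})
    out = set()
    for s in sorted(set(sources)):
        for m in mids:
            c1 = counts.get((s, m), 0)
            if c1 < threshold:
                continue
            for t in sorted(set(targets)):
                c2 = counts.get((m, t), 0)
                if c2 >= threshold:
                    out.add((s, m, t, c1, c2))
    return out


class TestThresholds:
    def test_defaults_encode_the_strict_inequalities(self):
        t = Thresholds()
        assert (t.significant, t.strong, t.relaxed) == (5, 10, 3)
        assert (t.top_partner, t.descending_focus) == (80, 50)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            Thresholds(significant=2, strong=10, relaxed=3)


class TestAggregateEdges:
    ann = make_annotations(
        [
            ("a1", "A", "left", 0, 0, 0),
            ("a2", "A", "left", 1, 0, 0),
            ("b1", "B", "left", 2, 0, 0),
            ("b2", "B", "right", 3, 0, 0),
        ]
    )
    grouping = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_four_excluded_five_included(self):
        syn = make_synapses([("a1", "b1", 4), ("a2", "b1", 5)])
        edges = aggregate_edges(syn, self.grouping, threshold=5, annotations=self.ann)
        assert len(edges) == 1
        assert edges.iloc[0]["n_pairs"] == 1
        assert edges.iloc[0]["total_synapses"] == 5

    def test_survivor_sums_and_mean(self):
        syn = make_synapses([("a1", "b1", 5), ("a2", "b1", 7)])
        edges = aggregate_edges(syn, self.grouping, threshold=5, annotations=self.ann)
        row = edges.iloc[0]
        assert (row["n_pairs"], row["total_synapses"]) == (2, 12)
        assert row["mean_synapses_per_pair"] == pytest.approx(6.0)

    def test_laterality_buckets(self):
        syn = make_synapses([("a1", "b1", 5), ("a1", "b2", 6)])
        edges = aggregate_edges(syn, self.grouping, threshold=5, annotations=self.ann)
        row = edges.iloc[0]
        assert row["ipsi_synapses"] == 5 and row["contra_synapses"] == 6
        assert row["ipsi_synapses"] + row["contra_synapses"] == row["total_synapses"]

    def test_missing_neuron_routed_to_other(self):
        syn = make_synapses([("a1", "zz", 9)])
        with pytest.warns(UserWarning, match="other"):
            edges = aggregate_edges(syn, self.grouping, threshold=5)
        assert edges.iloc[0]["post_cluster"] == "other"

    def test_fixture_recovery_against_ground_truth(self, connectome):
        gt = connectome.ground_truth
        grouping = {nid: ct for nid, (_, ct) in gt.true_roster.items()}
        edges = aggregate_edges(
            connectome.synapses, grouping, threshold=5, annotations=connectome.neurons
        )
        edges = edges[
            (edges["pre_cluster"] != "other") & (edges["post_cluster"] != "other")
        ]
        found = set()
        for r in edges.itertuples(index=False):
            lat = (
                "both"
                if r.ipsi_synapses and r.contra_synapses
                else ("ipsi" if r.ipsi_synapses else "contra")
            )
            found.add((r.pre_cluster, r.post_cluster, lat))
        assert found == gt.planted_cluster_edges


class TestLateralityAndBreakdown:
    def test_split_example(self):
        ann = make_annotations(
            [("a", "A", "left", 0, 0, 0), ("b", "B", "right", 1, 0, 0), ("c", "C", "left", 2, 0, 0)]
        )
        syn = make_synapses([("a", "b", 6), ("a", "c", 5)])
        out = laterality_split(syn, ann)
        assert (out["ipsi"], out["contra"]) == (5, 6)

    def test_breakdown_fractions(self):
        ann = make_annotations(
            [
                ("t", "T", "left", 0, 0, 0, "central"),
                ("p1", "P", "left", 1, 0, 0, "central"),
                ("p2", "P", "left", 2, 0, 0, "optic"),
            ]
        )
        syn = make_synapses([("p1", "t", 70), ("p2", "t", 30)])
        frac = superclass_breakdown(syn, ann, ["t"], direction="in")
        assert frac["central"] == pytest.approx(0.7)
        assert frac["optic"] == pytest.approx(0.3)
        assert frac.sum() == pytest.approx(1.0)

    def test_single_class_gets_fraction_one(self):
        ann = make_annotations(
            [("t", "T", "left", 0, 0, 0, "central"), ("p", "P", "left", 1, 0, 0, "optic")]
        )
        syn = make_synapses([("t", "p", 12)])
        frac = superclass_breakdown(syn, ann, ["t"], direction="out")
        assert dict(frac) == {"optic": pytest.approx(1.0)}

    def test_empty_edges_give_empty_breakdown(self):
        ann = make_annotations([("t", "T", "left", 0, 0, 0)])
        frac = superclass_breakdown(make_synapses([]), ann, ["t"])
        assert len(frac) == 0

    def test_conservation_between_buckets(self, connectome):
        # sum of laterality buckets equals total thresholded synapses
        out = laterality_split(connectome.synapses, connectome.neurons, threshold=5)
        pairs = pair_counts(connectome.synapses)
        total = int(pairs[pairs["n_synapses"] >= 5]["n_synapses"].sum())
        assert out["ipsi"] + out["contra"] + out["unassigned"] == total


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert cosine_similarity([1, 0, 2, 0], [0, 3, 0, 4]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity([0, 0], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.1, 5.0, size=8)
        b = rng.uniform(0.1, 5.0, size=8)
        dot = sum(x * y for x, y in zip(a, b))
        na = math.sqrt(sum(x * x for x in a))
        nb = math.sqrt(sum(y * y for y in b))
        assert cosine_similarity(a, b) == pytest.approx(dot / (na * nb))


class TestProfileClustering:
    def _two_archetypes(self):
        # archetype 1 talks to m1/m2, archetype 2 to m3/m4
        rows = []
        for n in ("p1", "p2", "p1c"):  # p1c is an exact clone of p1's pattern
            rows += [(n, "m1", 10), (n, "m2", 6), ("m1", n, 4)]
        for n in ("q1", "q2"):
            rows += [(n, "m3", 9), (n, "m4", 7), ("m4", n, 3)]
        return make_synapses(rows)

    def test_identical_profiles_merge_at_zero(self):
        syn = self._two_archetypes()
        profiles = build_profiles(syn, ["p1", "p1c", "q1"])
        clustering = cluster_profiles(profiles)
        assert clustering.cophenetic_height("p1", "p1c") == pytest.approx(0.0, abs=1e-12)

    def test_two_archetypes_separate_at_two_cut(self):
        syn = self._two_archetypes()
        profiles = build_profiles(syn, ["p1", "p2", "p1c", "q1", "q2"])
        labels = cluster_profiles(profiles).cut(2)
        assert labels["p1"] == labels["p2"] == labels["p1c"]
        assert labels["q1"] == labels["q2"]
        assert labels["p1"] != labels["q1"]

    def test_input_order_invariance(self):
        syn = self._two_archetypes()
        ids = ["p1", "p2", "p1c", "q1", "q2"]
        a = cluster_profiles(build_profiles(syn, ids)).to_newick()
        b = cluster_profiles(build_profiles(syn, ids[::-1])).to_newick()
        assert a == b

    def test_fewer_than_two_profiles_rejected(self):
        syn = self._two_archetypes()
        with pytest.raises(ValueError):
            cluster_profiles(build_profiles(syn, ["p1"]))

    def test_newick_has_all_leaves(self):
        syn = self._two_archetypes()
        nwk = cluster_profiles(build_profiles(syn, ["p1", "p2", "q1"])).to_newick()
        for leaf in ("p1", "p2", "q1"):
            assert leaf in nwk
        assert nwk.endswith(";")


class TestDisynaptic:
    def test_chain_reported(self):
        syn = make_synapses([("a", "b", 5), ("b", "c", 5)])
        paths = disynaptic_connections(["a"], ["c"], syn, threshold=5)
        assert paths[["source", "mid", "target"]].values.tolist() == [["a", "b", "c"]]

    def test_threshold_relaxation_reveals_path(self):
        syn = make_synapses([("a", "b", 5), ("b", "c", 4)])
        assert len(disynaptic_connections(["a"], ["c"], syn, threshold=5)) == 0
        assert len(disynaptic_connections(["a"], ["c"], syn, threshold=3)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("threshold", [3, 5])
    def test_matches_brute_force_enumeration(self, seed, threshold):
        rng = np.random.default_rng(seed)
        syn, ids = random_synapse_table(rng, n_neurons=40, p=0.12)
        sources = ids[:10]
        targets = ids[-10:]
        got = {
            (r.source, r.mid, r.target, r.hop1_synapses, r.hop2_synapses)
            for r in disynaptic_connections(sources, targets, syn, threshold).itertuples(
                index=False
            )
        }
        assert got == brute_force_disynaptic(sources, targets, syn, threshold)

    def test_summary_means_per_pair(self):
        syn = make_synapses([("a", "b", 5), ("a2", "b", 7), ("b", "c", 6)])
        paths = disynaptic_connections(["a", "a2"], ["c"], syn, threshold=5)
        summary = summarize_disynaptic(paths, {"a": "S", "a2": "S", "b": "M", "c": "T"})
        row = summary.iloc[0]
        assert row["n_paths"] == 2
        assert row["mean_hop1_synapses_per_pair"] == pytest.approx(6.0)
        assert row["mean_hop2_synapses_per_pair"] == pytest.approx(6.0)


class TestTopPartnersFanInShare:
    def test_79_is_excluded_at_80(self):
        syn = make_synapses([("u", "f", 79), ("v", "f", 80)])
        out = top_partners(syn, ["f"], direction="in", min_total=80)
        assert out["partner"].tolist() == ["v"]

    def test_hub_ranked_first(self):
        syn = make_synapses([("hub", "f1", 60), ("hub", "f2", 40), ("w", "f1", 85)])
        out = top_partners(syn, ["f1", "f2"], direction="in", min_total=80)
        assert out["partner"].tolist() == ["hub", "w"]
        assert out["total_synapses"].tolist() == [100, 85]

    def test_empty_edges(self):
        out = top_partners(make_synapses([]), ["f"], min_total=80)
        assert len(out) == 0

    def test_fan_in_worked_values(self):
        assert fan_in_estimate(300, 3, 3) == pytest.approx(300.0)
        assert fan_in_estimate(300, 3, 1) == pytest.approx(100.0)
        assert fan_in_estimate(0, 3, 3) == 0.0

    def test_fan_in_zero_downstream_rejected(self):
        with pytest.raises(ValueError):
            fan_in_estimate(300, 0, 3)

    def test_input_share_quarter(self):
        syn = make_synapses([("s", "t", 25), ("x", "t", 75)])
        assert input_share(syn, "t", ["s"]) == pytest.approx(0.25)

    def test_input_share_all(self):
        syn = make_synapses([("s", "t", 10)])
        assert input_share(syn, "t", ["s"]) == pytest.approx(1.0)

    def test_input_share_no_inputs_rejected(self):
        with pytest.raises(ValueError):
            input_share(make_synapses([("t", "s", 5)]), "t", ["s"])


@given(st.integers(0, 2**31 - 1), st.integers(1, 8))
@settings(max_examples=20, deadline=None)
def test_edge_and_path_sets_monotone_in_threshold(seed, threshold):
    """Stricter synapse thresholds can only remove edges and paths."""
    rng = np.random.default_rng(seed)
    syn, ids = random_synapse_table(rng, n_neurons=15, p=0.2, max_count=10)
    grouping = {i: f"c{int(i[1:]) % 4}" for i in ids}
    strict = aggregate_edges(syn, grouping, threshold=threshold + 1)
    loose = aggregate_edges(syn, grouping, threshold=threshold)
    strict_keys = {(r.pre_cluster, r.post_cluster) for r in strict.itertuples(index=False)}
    loose_keys = {(r.pre_cluster, r.post_cluster) for r in loose.itertuples(index=False)}
    assert strict_keys <= loose_keys

    sources, targets = ids[:5], ids[-5:]
    p_strict = disynaptic_connections(sources, targets, syn, threshold + 1)
    p_loose = disynaptic_connections(sources, targets, syn, threshold)
    ks = {tuple(r) for r in p_strict[["source", "mid", "target"]].values}
    kl = {tuple(r) for r in p_loose[["source", "mid", "target"]].values}
    assert ks <= kl
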