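import pytest

from memtype import (
    CascadeConfig,
    MembraneType,
    predict_by_rwc,
    predict_integrated,
    rwc_scores,
)
from memtype.homology import AlignmentHit
from conftest import make_dataset, make_interactions, random_protein_sequence
from test_homology import StubProvider

T = MembraneType


@pytest.fixture
def training(rng):
    return make_dataset(
        ("a", random_protein_sequence(rng, 60), {T.MULTI_PASS}),
        ("b", random_protein_sequence(rng, 60), {T.PERIPHERAL}),
        ("c", random_protein_sequence(rng, 60), {T.SINGLE_PASS_I}),
    )


def query_with_sequence(rng):
    return make_dataset(("q", random_protein_sequence(rng, 60), None))["q"]


class TestCascade:
    def test_passing_homolog_preempts_network(self, rng, training):
        query = query_with_sequence(rng)
        provider = StubProvider([AlignmentHit("q", "a", score=200, evalue=1e-30)])
        interactions = make_interactions(("q", "b", 900))
        pred = predict_integrated(query, training, provider, interactions)
        assert pred.stage == "homology"
        assert pred.labels == frozenset({T.MULTI_PASS})

    def test_no_homolog_with_partner_fires_network(self, rng, training):
        query = query_with_sequence(rng)
        provider = StubProvider([])
        interactions = make_interactions(("q", "b", 900))
        pred = predict_integrated(query, training, provider, interactions)
        assert pred.stage == "network"
        assert pred.labels == frozenset({T.PERIPHERAL})

    def test_two_hop_reachable_fires_shortest_distance(self, rng, training):
        query = query_with_sequence(rng)
        provider = StubProvider([])
        interactions = make_interactions(("q", "x", 900), ("x", "b", 800))
        pred = predict_integrated(query, training, provider, interactions)
        assert pred.stage == "shortest_distance"
        assert pred.labels == frozenset({T.PERIPHERAL})

    def test_empty_interactions_degenerate_to_homology_plus_fallback(self, rng, training):
        query = query_with_sequence(rng)
        with_hit = StubProvider([AlignmentHit("q", "c", score=200, evalue=1e-30)])
        assert predict_integrated(query, training, with_hit).stage == "homology"
        no_hit = StubProvider([])
        pred = predict_integrated(query, training, no_hit)
        assert pred.stage == "shortest_distance"
        assert pred.fallback

    def test_sequence_less_query_skips_homology(self, training):
        query = make_dataset(("q", "", None))["q"]
        interactions = make_interactions(("q", "c", 700))
        pred = predict_integrated(query, training, StubProvider([]), interactions)
        assert pred.stage == "network"
        assert pred.labels == frozenset({T.SINGLE_PASS_I})

    def test_exactly_one_stage_fires_per_protein(self, rng, training):
        """Stage assignment partitions any query set."""
        interactions = make_interactions(("q1", "b", 900), ("q2", "x", 900), ("x", "a", 800))
        provider = StubProvider([AlignmentHit("q0", "a", score=300, evalue=1e-40)])
        stages = []
        for qid in ("q0", "q1", "q2", "q3"):
            query = make_dataset((qid, random_protein_sequence(rng, 60), None))[qid]
            stages.append(predict_integrated(query, training, provider, interactions).stage)
        assert stages == ["homology", "network", "shortest_distance", "shortest_distance"]


class TestRwcScore:
    def test_dominant_candidate_scores_one(self, rng):
        training = make_dataset(("a", "A" * 60, {T.MULTI_PASS}),
                                ("b", "C" * 60, {T.PERIPHERAL}))
        query = make_dataset(("q", "A" * 60, None))["q"]
        provider = StubProvider([AlignmentHit("q", "a", score=300, evalue=1e-40),
                                 AlignmentHit("q", "b", score=20, evalue=5)])
        interactions = make_interactions(("q", "a", 990), ("q", "b", 200))
        scores = rwc_scores(query, training, provider, interactions)
        assert scores["a"] == pytest.approx(1.0)
        assert scores["b"] == pytest.approx(0.0)

    def test_hand_weighted_arithmetic(self, rng):
        # candidate a: best alignment only; candidate b: best confidence and
        # best (smallest) shortest distance -> 1/3 vs 2/3 at equal weights
        training = make_dataset(("a", "A" * 60, {T.MULTI_PASS}),
                                ("b", "C" * 60, {T.PERIPHERAL}))
        query = make_dataset(("q", "A" * 60, None))["q"]
        provider = StubProvider([AlignmentHit("q", "a", score=300, evalue=1e-40),
                                 AlignmentHit("q", "b", score=10, evalue=8)])
        interactions = make_interactions(("q", "a", 300), ("q", "b", 900))
        scores = rwc_scores(query, training, provider, interactions)
        assert scores["a"] == pytest.approx(1 / 3)
        assert scores["b"] == pytest.approx(2 / 3)

    def test_all_components_missing_everywhere_is_an_error(self):
        training = make_dataset(("a", "", {T.MULTI_PASS}))
        query = make_dataset(("q", "", None))["q"]
        with pytest.raises(ValueError, match="undefined"):
            rwc_scores(query, training, provider=None)

    def test_invariant_to_affine_rescaling_of_alignment_scores(self, rng, training):
        query = query_with_sequence(rng)
        base_hits = [AlignmentHit("q", pid, score=s, evalue=1e-10)
                     for pid, s in (("a", 120.0), ("b", 45.0), ("c", 260.0))]
        rescaled = [AlignmentHit("q", h.subject_id, score=3.5 * h.score + 40,
                                 evalue=h.evalue) for h in base_hits]
        interactions = make_interactions(("q", "a", 400), ("q", "b", 700))
        s1 = rwc_scores(query, training, StubProvider(base_hits), interactions)
        s2 = rwc_scores(query, training, StubProvider(rescaled), interactions)
        assert s1 == pytest.approx(s2)


class TestPredictByRwc:
    def test_single_candidate_donates_labels(self):
        training = make_dataset(("a", "", {T.MULTI_PASS, T.PERIPHERAL}))
        query = make_dataset(("q", "", None))["q"]
        interactions = make_interactions(("q", "a", 500))
        pred = predict_by_rwc(query, training, interactions=interactions)
        assert pred.labels == frozenset({T.MULTI_PASS, T.PERIPHERAL})

    def test_argmax_candidate_wins(self, rng, training):
        query = query_with_sequence(rng)
        provider = StubProvider([AlignmentHit("q", "a", score=300, evalue=1e-40),
                                 AlignmentHit("q", "b", score=10, evalue=8)])
        interactions = make_interactions(("q", "a", 300), ("q", "b", 900))
        pred = predict_by_rwc(query, training, provider, interactions)
        assert pred.diagnostics["best_candidate"] == "b"
        assert pred.labels == frozenset({T.PERIPHERAL})

    def test_fused_score_can_prefer_a_wrong_neighbor(self):
        """A strongly connected but differently-typed hub can mislead RWC
        while the cascade's network vote still gets the query right."""
        training = make_dataset(
            ("hub", "", {T.SINGLE_PASS_I}),
            ("p1", "", {T.MULTI_PASS}),
            ("p2", "", {T.MULTI_PASS}),
        )
        query = make_dataset(("q", "", None))["q"]
        # one very confident edge to the wrong-type hub, two moderate edges
        # to same-type partners whose combined mass outweighs the hub
        interactions = make_interactions(
            ("q", "hub", 990), ("q", "p1", 600), ("q", "p2", 600))
        rwc_pred = predict_by_rwc(query, training, interactions=interactions)
        assert rwc_pred.labels == frozenset({T.SINGLE_PASS_I})  # misled

        cascade = predict_integrated(query, training, StubProvider([]),
                                     interactions, CascadeConfig(t=1))
        assert cascade.stage == "network"
        assert cascade.labels == frozenset({T.MULTI_PASS})  # weighted vote is right
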