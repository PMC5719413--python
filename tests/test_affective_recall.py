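import numpy as np
import pytest

from recallnet import (
    AffectParams,
    RecallnetError,
    StructuralParams,
    corrupt_seed_valences,
    incident_edges,
    score_quality,
    simulate_affective_recall,
    simulate_recall,
    simulate_structural_recall,
    valence_for_new_tie,
)
from recallnet.signed_network import normalize_edge


def seed_truth(net, characters):
    return {e: net.valence[e] for e in incident_edges(net, characters)}


class TestCorruption:
    def test_x_zero_keeps_all_valences(self, balanced_fixture):
        truth = seed_truth(balanced_fixture, {"Lewis", "Alyssa"})
        out = corrupt_seed_valences(truth, AffectParams(x=0.0), np.random.default_rng(0))
        assert out == truth

    def test_x_030_redraws_exactly_three_of_nine(self, balanced_fixture):
        # round-half-up: round(0.30 * 9) = 3, so at most 3 valences can differ
        truth = seed_truth(balanced_fixture, {"Lewis", "Alyssa"})
        assert len(truth) == 9
        diffs = []
        for rep in range(300):
            out = corrupt_seed_valences(
                truth, AffectParams(x=0.30), np.random.default_rng(rep)
            )
            diffs.append(sum(1 for e in truth if out[e] != truth[e]))
        assert max(diffs) == 3  # a redraw can also match by chance
        assert min(diffs) >= 0

    def test_x_one_redraw_matches_truth_about_half_the_time(self, balanced_fixture):
        truth = seed_truth(balanced_fixture, {"Lewis", "Alyssa"})
        edges = sorted(truth)
        match = np.zeros(len(edges))
        reps = 1000
        for rep in range(reps):
            out = corrupt_seed_valences(
                truth, AffectParams(x=1.0), np.random.default_rng(rep)
            )
            match += [out[e] == truth[e] for e in edges]
        rates = match / reps
        assert np.all(np.abs(rates - 0.5) < 0.05)

    def test_rounding_is_half_up(self):
        truth = {("a", "b"): 1, ("a", "c"): 1}
        # x = 0.25 on 2 edges: 0.5 rounds up to 1 redraw
        diffs = set()
        for rep in range(200):
            out = corrupt_seed_valences(
                truth, AffectParams(x=0.25), np.random.default_rng(rep)
            )
            diffs.add(sum(1 for e in truth if out[e] != truth[e]))
        assert diffs <= {0, 1} and 1 in diffs

    def test_reproducible(self, balanced_fixture):
        truth = seed_truth(balanced_fixture, {"Peter"})
        a = corrupt_seed_valences(truth, AffectParams(x=0.5), np.random.default_rng(7))
        b = corrupt_seed_valences(truth, AffectParams(x=0.5), np.random.default_rng(7))
        assert a == b


class TestValenceRule:
    def test_single_positive_triplet(self):
        valences = {normalize_edge("u", "w"): 1, normalize_edge("v", "w"): 1}
        assert valence_for_new_tie(valences, ("u", "v")) == 1

    def test_single_mixed_triplet(self):
        valences = {normalize_edge("u", "w"): 1, normalize_edge("v", "w"): -1}
        assert valence_for_new_tie(valences, ("u", "v")) == -1

    def test_no_triplet_positivity_bias(self):
        valences = {normalize_edge("a", "b"): -1}
        assert valence_for_new_tie(valences, ("u", "v")) == 1

    def test_two_triplet_tie_defaults_positive(self):
        valences = {
            normalize_edge("u", "w1"): 1,
            normalize_edge("v", "w1"): 1,
            normalize_edge("u", "w2"): 1,
            normalize_edge("v", "w2"): -1,
        }
        assert valence_for_new_tie(valences, ("u", "v")) == 1

    def test_two_triplet_tie_negative_tiebreak(self):
        valences = {
            normalize_edge("u", "w1"): 1,
            normalize_edge("v", "w1"): 1,
            normalize_edge("u", "w2"): 1,
            normalize_edge("v", "w2"): -1,
        }
        params = AffectParams(zero_tiebreak="negative")
        assert valence_for_new_tie(valences, ("u", "v"), params) == -1

    def test_majority_over_three_triplets(self):
        valences = {}
        for w, sign in (("w1", 1), ("w2", 1), ("w3", -1)):
            valences[normalize_edge("u", w)] = 1
            valences[normalize_edge("v", w)] = sign
        assert valence_for_new_tie(valences, ("u", "v")) == 1


class TestAffectivePass:
    def test_valence_covers_exactly_recalled_edges(self, balanced_fixture):
        rng = np.random.default_rng(5)
        result = simulate_recall(balanced_fixture, {"Lewis", "Alyssa"}, rng=rng)
        assert set(result.valence) == result.edges

    def test_edge_set_unchanged(self, balanced_fixture):
        rng = np.random.default_rng(5)
        structural = simulate_structural_recall(
            balanced_fixture, {"Lewis", "Alyssa"}, rng=rng
        )
        valenced = simulate_affective_recall(
            balanced_fixture, structural, rng=np.random.default_rng(6)
        )
        assert valenced.edges == structural.edges
        assert valenced.seed_edges == structural.seed_edges

    def test_uncorrupted_balanced_recall_has_perfect_quality(self, balanced_fixture):
        # on a fully balanced target with x=0 and closure-driven additions
        # only, balance propagation can never mislabel a true tie
        params = AffectParams(x=0.0)
        for rep in range(30):
            result = simulate_recall(
                balanced_fixture,
                {"Lewis", "Alyssa"},
                affect_params=params,
                rng=np.random.default_rng(rep),
            )
            assert score_quality(balanced_fixture, result) == 1.0

    @pytest.mark.parametrize(
        "side_valences, expected",
        [((1, 1), 1), ((-1, -1), 1), ((1, -1), -1)],
    )
    def test_closing_tie_takes_sign_product_of_sides(self, side_valences, expected):
        # seeds covering two sides of a triangle: the closing tie's valence
        # is the sign product of the two exactly recalled sides
        from recallnet import SignedNetwork

        va, vc = side_valences
        target = SignedNetwork.from_edges(
            [("a", "b", va), ("b", "c", vc), ("a", "c", expected)]
        )
        structural = StructuralParams(p_triangle=1.0, p_background=0.0)
        result = simulate_recall(
            target, {"b"}, structural, AffectParams(x=0.0), np.random.default_rng(0)
        )
        assert result.edges == {("a", "b"), ("a", "c"), ("b", "c")}
        assert result.valence[("a", "c")] == expected

    def test_foreign_structural_result_rejected(self, balanced_fixture):
        from recallnet.structural_recall import RecalledNetwork

        foreign = RecalledNetwork(edges={("a", "b")}, seed_edges={("a", "b")})
        with pytest.raises(RecallnetError):
            simulate_affective_recall(
                balanced_fixture, foreign, rng=np.random.default_rng(0)
            )

    def test_positivity_only_when_no_closed_triplets(self, balanced_fixture):
        # background-only additions never close triplets when there are no
        # seeds, so every recalled valence is +1
        structural = StructuralParams(p_triangle=0.0, p_background=0.3,
                                      closure_against="seed_only")
        result = simulate_recall(
            balanced_fixture,
            set(),
            structural,
            AffectParams(x=0.0),
            np.random.default_rng(2),
        )
        assert result.edges  # background produced some ties
        assert all(v == 1 for v in result.valence.values())
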