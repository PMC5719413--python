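import dataclasses

import pytest

from recallnet import (
    GenerationError,
    SignedNetwork,
    balance_report,
    canonical_fixture,
    components,
    default_fixture_spec,
    generate_fixture,
    incident_edges,
    table1_seed_sets,
    validate_fixture,
)
from recallnet.stimulus_fixtures import FixtureSpec
from conftest import make_net


class TestDefaultSpec:
    def test_canonical_counts(self):
        spec = default_fixture_spec("balanced")
        assert spec.n_edges == 23
        assert spec.n_positive == 15
        assert spec.n_negative == 8
        assert spec.n_components == 2

    def test_degree_constraints(self):
        spec = default_fixture_spec("balanced")
        assert spec.degree_constraints["Peter"] == 5
        assert spec.degree_constraints["Isabelle"] == 2

    def test_hubs_in_different_components(self):
        spec = default_fixture_spec("imbalanced")
        assert spec.hub_assignment["Lewis"] != spec.hub_assignment["Alyssa"]

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            default_fixture_spec("chaotic")

    def test_yaml_round_trip(self, tmp_path):
        spec = default_fixture_spec("balanced")
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert FixtureSpec.from_yaml(path) == spec


class TestGeneration:
    @pytest.mark.parametrize("condition", ["balanced", "imbalanced"])
    def test_generator_output_passes_validator(self, condition):
        spec = default_fixture_spec(condition)
        net = generate_fixture(spec)
        assert validate_fixture(net, spec) == []

    def test_two_components(self):
        net = generate_fixture(default_fixture_spec("balanced"))
        assert len(components(net)) == 2

    def test_lewis_alyssa_incident_count(self):
        net = generate_fixture(default_fixture_spec("balanced"))
        assert len(incident_edges(net, {"Lewis", "Alyssa"})) == 9

    def test_deterministic_given_seed(self):
        spec = default_fixture_spec("imbalanced")
        assert generate_fixture(spec) == generate_fixture(spec)

    def test_seed_changes_free_choices(self):
        spec = default_fixture_spec("balanced")
        other = dataclasses.replace(spec, rng_seed=spec.rng_seed + 1)
        # both valid; the free choices need not coincide
        assert validate_fixture(generate_fixture(other), other) == []

    def test_packaged_fixture_matches_regeneration(self):
        for condition in ("balanced", "imbalanced"):
            spec = default_fixture_spec(condition)
            assert generate_fixture(spec) == canonical_fixture(condition)

    def test_random_fixture_without_degree_constraints(self):
        spec = FixtureSpec(
            n_nodes=8,
            n_edges=10,
            n_positive=7,
            n_negative=3,
            n_components=2,
            component_sizes=(5, 3),
            condition="balanced",
            rng_seed=11,
        )
        net = generate_fixture(spec)
        assert validate_fixture(net, spec) == []

    def test_unsupported_degree_constraints_raise(self):
        spec = dataclasses.replace(
            default_fixture_spec("balanced"),
            degree_constraints={"Lewis": 7},
        )
        with pytest.raises(GenerationError):
            generate_fixture(spec)


class TestValidation:
    def test_flipped_valence_reported_as_balance_violation(self, balanced_fixture):
        spec = default_fixture_spec("balanced")
        tampered = balanced_fixture.copy()
        # flip one edge of a triangle: Henry-Elizabeth-James is mutually tied
        edge = ("Elizabeth", "Henry")
        tampered.valence[edge] = -tampered.valence[edge]
        violations = validate_fixture(tampered, spec)
        assert any("balance" in v for v in violations)

    def test_wrong_degree_reported(self, balanced_fixture):
        spec = default_fixture_spec("balanced")
        bad_spec = dataclasses.replace(
            spec, degree_constraints={**spec.degree_constraints, "Isabelle": 3}
        )
        violations = validate_fixture(balanced_fixture, bad_spec)
        assert any("Isabelle" in v and "degree" in v for v in violations)

    def test_violations_name_observed_values(self, balanced_fixture):
        spec = dataclasses.replace(default_fixture_spec("balanced"), n_edges=22,
                                   n_positive=14)
        violations = validate_fixture(balanced_fixture, spec)
        assert any("expected 22" in v and "observed 23" in v for v in violations)


class TestBalanceReport:
    def test_all_positive_triangle_balanced(self):
        net = make_net([("a", "b"), ("b", "c"), ("a", "c")])
        report = balance_report(net)
        assert (report.n_triangles, report.n_imbalanced_triangles) == (1, 0)

    def test_single_negative_triangle_imbalanced(self):
        net = make_net(
            [("a", "b"), ("b", "c"), ("a", "c")], valences={("a", "b"): -1}
        )
        assert balance_report(net).n_imbalanced_triangles == 1

    def test_two_negative_triangle_balanced(self):
        net = make_net(
            [("a", "b"), ("b", "c"), ("a", "c")],
            valences={("a", "b"): -1, ("b", "c"): -1},
        )
        assert balance_report(net).n_imbalanced_triangles == 0

    def test_canonical_conditions(self, balanced_fixture, imbalanced_fixture):
        assert balance_report(balanced_fixture).n_imbalanced_triangles == 0
        assert balance_report(imbalanced_fixture).n_imbalanced_triangles >= 1

    def test_counts_are_conserved_across_conditions(
        self, balanced_fixture, imbalanced_fixture
    ):
        def counts(net: SignedNetwork):
            pos = sum(1 for v in net.valence.values() if v > 0)
            return pos, net.n_edges - pos

        assert counts(balanced_fixture) == counts(imbalanced_fixture) == (15, 8)


class TestTable1Catalogue:
    def test_thirty_five_rows_in_order(self):
        rows = table1_seed_sets()
        assert len(rows) == 35
        assert rows[0] == (("Isabelle",), 2)
        assert rows[-1] == (("Peter", "Alyssa", "Victoria"), 12)

    def test_all_incident_counts_reproduce(self, balanced_fixture, imbalanced_fixture):
        for net in (balanced_fixture, imbalanced_fixture):
            for chars, expected in table1_seed_sets():
                assert len(incident_edges(net, chars)) == expected
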