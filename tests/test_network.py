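"""Network construction, parsing, mass-action kinetics and derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from insulinit.network import (
    NetworkParseError,
    ParameterVector,
    Reaction,
    ReactionNetwork,
    Species,
    UnsupportedConstructError,
    export_summary,
    jacobian_and_dfdk,
    massaction_rate,
    parse_network,
    rhs,
    split_reversible,
    write_network,
)
from insulinit.synthetic import random_network


class TestStructure:
    def test_stoichiometric_matrix_signs(self):
        net = ReactionNetwork(
            [Species("A"), Species("B"), Species("C")],
            [Reaction("r", (("A", 1), ("B", 1)), (("C", 1),), 2.0)],
        )
        assert net.S[:, 0].tolist() == [-1, -1, 1]

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ReactionNetwork([Species("A"), Species("A")], [])

    def test_unknown_reaction_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            ReactionNetwork([Species("A")], [Reaction("r", (("B", 1),), ())])

    def test_negative_initial_amount_rejected(self):
        with pytest.raises(ValueError):
            Species("A", initial_amount=-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_S_consistent_with_reactions(self, seed):
        net = random_network(8, 14, seed)
        S = np.zeros_like(net.S)
        for j, rxn in enumerate(net.reactions):
            for sid, c in rxn.reactants:
                S[net.index[sid], j] -= c
            for sid, c in rxn.products:
                S[net.index[sid], j] += c
        np.testing.assert_array_equal(S, net.S)


class TestSplitReversible:
    def test_reversible_pair_splits(self):
        net = ReactionNetwork(
            [Species("A", initial_amount=1.0), Species("B")],
            [Reaction("r", (("A", 1),), (("B", 1),), 1.0, True, 2.0)],
        )
        out = split_reversible(net)
        assert out.n_reactions == 2
        f, r = out.reactions
        assert not f.reversible and not r.reversible
        assert f.rate_constant == 1.0 and r.rate_constant == 2.0
        assert f.reactants == (("A", 1),) and r.reactants == (("B", 1),)

    def test_counting_and_identity(self):
        rev = [
            Reaction(f"v{i}", (("A", 1),), (("B", 1),), 1.0, True, 1.0)
            for i in range(3)
        ]
        irr = [Reaction("w", (("B", 1),), (("A", 1),), 1.0)]
        net = ReactionNetwork([Species("A"), Species("B")], rev + irr)
        out = split_reversible(net)
        assert out.n_reactions == 4 + 3  # R + m
        # no reversible reactions -> identity
        same = split_reversible(out)
        assert [r.id for r in same.reactions] == [r.id for r in out.reactions]

    def test_idempotent(self):
        net = ReactionNetwork(
            [Species("A"), Species("B")],
            [Reaction("r", (("A", 1),), (("B", 1),), 1.0, True, 2.0)],
        )
        once = split_reversible(net)
        twice = split_reversible(once)
        assert [r.id for r in once.reactions] == [r.id for r in twice.reactions]


class TestMassActionRate:
    def test_bimolecular(self):
        r = Reaction("r", (("A", 1), ("B", 1)), (("C", 1),), 2.0)
        assert massaction_rate(r, np.array([3.0, 4.0, 0.0]), {"A": 0, "B": 1, "C": 2}) == 24.0

    def test_second_order_exponent(self):
        r = Reaction("r", (("A", 2),), (("B", 1),), 1.0)
        assert massaction_rate(r, np.array([3.0, 0.0]), {"A": 0, "B": 1}) == 9.0

    def test_zeroth_order_source(self):
        r = Reaction("r", (), (("A", 1),), 0.5)
        assert massaction_rate(r, np.array([7.0]), {"A": 0}) == 0.5

    def test_negative_concentration_rejected(self):
        r = Reaction("r", (("A", 1),), (), 1.0)
        with pytest.raises(ValueError, match="negative"):
            massaction_rate(r, np.array([-0.1]), {"A": 0})


class TestRHS:
    def test_single_reaction_balance(self):
        net = ReactionNetwork(
            [Species("A", initial_amount=1.0), Species("B")],
            [Reaction("r", (("A", 1),), (("B", 1),), 1.0)],
        )
        np.testing.assert_allclose(
            rhs(net, np.array([1.0, 0.0]), np.array([1.0])), [-1.0, 1.0]
        )

    def test_dimension_mismatch(self):
        net = ReactionNetwork([Species("A")], [Reaction("r", (("A", 1),), ())])
        with pytest.raises(ValueError, match="shape"):
            rhs(net, np.array([1.0, 2.0]), np.array([1.0]))

    @pytest.mark.parametrize("seed", range(4))
    def test_mass_conservation_closed_networks(self, seed, rng):
        net = random_network(7, 12, seed, closed=True)
        assert (net.S.sum(axis=0) == 0).all()
        for _ in range(5):
            x = rng.uniform(0, 3, net.n_species)
            dx = rhs(net, x, net.rate_constants)
            assert abs(dx.sum()) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_summation_oracle(self, seed, rng):
        net = random_network(6, 11, seed)
        x = rng.uniform(0, 2, net.n_species)
        k = rng.uniform(0, 3, net.n_reactions)
        expected = np.zeros(net.n_species)
        for j, rxn in enumerate(net.reactions):
            rate = k[j]
            for sid, c in rxn.reactants:
                rate *= x[net.index[sid]] ** c
            for sid, c in rxn.reactants:
                expected[net.index[sid]] -= c * rate
            for sid, c in rxn.products:
                expected[net.index[sid]] += c * rate
        np.testing.assert_allclose(rhs(net, x, k), expected, rtol=1e-12)


def _fd_jacobians(net, x, k):
    """Central finite-difference oracle for J and B."""
    n, p = net.n_species, net.n_reactions
    J = np.empty((n, n))
    for i in range(n):
        h = 1e-6 * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (rhs(net, xp, k) - rhs(net, np.maximum(xm, 0), k)) / (xp[i] - max(xm[i], 0))
    B = np.empty((n, p))
    for j in range(p):
        h = 1e-6 * max(abs(k[j]), 1.0)
        kp, km = k.copy(), k.copy()
        kp[j] += h
        km[j] = max(km[j] - h, 0)
        B[:, j] = (rhs(net, x, kp) - rhs(net, x, km)) / (kp[j] - km[j])
    return J, B


class TestJacobian:
    def test_linear_decay_closed_form(self, decay_network):
        J, B = jacobian_and_dfdk(decay_network, np.array([3.0]), np.array([2.0]))
        assert J[0, 0] == -2.0
        assert B[0, 0] == -3.0

    def test_zero_rate_constants_zero_jacobian(self, toy_network):
        x = np.full(toy_network.n_species, 0.7)
        J, _ = jacobian_and_dfdk(toy_network, x, np.zeros(toy_network.n_reactions))
        assert np.all(J == 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_finite_differences(self, seed):
        rng = np.random.default_rng(seed + 100)
        n_s = int(rng.integers(4, 10))
        net = random_network(n_s, n_s - 1 + int(rng.integers(1, 8)), seed)
        x = rng.uniform(0.1, 2.0, net.n_species)
        k = rng.uniform(0.1, 3.0, net.n_reactions)
        J, B = jacobian_and_dfdk(net, x, k)
        Jfd, Bfd = _fd_jacobians(net, x, k)
        scale_J = np.abs(Jfd).max() or 1.0
        scale_B = np.abs(Bfd).max() or 1.0
        assert np.abs(J - Jfd).max() / scale_J < 1e-4
        assert np.abs(B - Bfd).max() / scale_B < 1e-4


class TestTextFormat:
    def test_parse_minimal(self, tmp_path):
        f = tmp_path / "net.txt"
        f.write_text("A = 1.0\nR1: A + B -> C ; k=2\n")
        net = parse_network(f)
        assert net.species_ids == ["A", "B", "C"]
        assert net.n_reactions == 1
        assert net.S[:, 0].tolist() == [-1, -1, 1]
        assert net.reactions[0].rate_constant == 2.0

    def test_reversible_and_coefficients(self, tmp_path):
        f = tmp_path / "net.txt"
        f.write_text("R1: A + 2*B <-> C ; kf=0.1, kr=0.4\n")
        net = parse_network(f)
        rxn = net.reactions[0]
        assert rxn.reversible and rxn.reverse_rate_constant == 0.4
        assert dict(rxn.reactants)["B"] == 2

    def test_round_trip_identity(self, tmp_path, toy_network):
        path = tmp_path / "toy.txt"
        write_network(toy_network, path)
        back = parse_network(path)
        assert back.species_ids == toy_network.species_ids
        assert back.reaction_ids == toy_network.reaction_ids
        np.testing.assert_array_equal(back.S, toy_network.S)
        np.testing.assert_allclose(back.rate_constants, toy_network.rate_constants)
        np.testing.assert_allclose(
            back.initial_conditions, toy_network.initial_conditions
        )

    def test_malformed_line_names_offender(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("R1: A -> B ; k=nope\n")
        with pytest.raises(NetworkParseError, match="nope"):
            parse_network(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_network(tmp_path / "absent.txt")


class TestSBML:
    def test_round_trip(self, tmp_path, toy_network):
        path = tmp_path / "toy.xml"
        write_network(toy_network, path)
        back = parse_network(path)
        assert back.species_ids == toy_network.species_ids
        assert back.reaction_ids == toy_network.reaction_ids
        np.testing.assert_array_equal(back.S, toy_network.S)
        np.testing.assert_allclose(back.rate_constants, toy_network.rate_constants)

    def test_unsupported_construct_is_explicit(self, tmp_path):
        path = tmp_path / "events.xml"
        path.write_text(
            '<?xml version="1.0"?>'
            '<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="4">'
            "<model id='m'><listOfEvents/></model></sbml>"
        )
        with pytest.raises(UnsupportedConstructError, match="listOfEvents"):
            parse_network(path, "sbml")

    def test_malformed_xml_names_file(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<sbml><model>")
        with pytest.raises(NetworkParseError, match="malformed"):
            parse_network(path, "sbml")


class TestParameterVector:
    def test_flat_layout_round_trip(self, toy_network):
        p = toy_network.nominal_parameters()
        flat = p.as_array()
        assert flat.size == toy_network.n_reactions + toy_network.n_species
        q = ParameterVector.from_array(flat, toy_network.n_reactions)
        np.testing.assert_array_equal(q.rate_constants, p.rate_constants)
        np.testing.assert_array_equal(q.initial_conditions, p.initial_conditions)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ParameterVector(np.array([-1.0]), np.array([0.0]))


def test_summary_export(tmp_path, toy_network):
    sp, rx = export_summary(toy_network, tmp_path)
    import pandas as pd

    species = pd.read_csv(sp)
    reactions = pd.read_csv(rx)
    assert len(species) == toy_network.n_species
    assert len(reactions) == toy_network.n_reactions


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=6))
def test_massaction_rate_scales_linearly_in_k(xs):
    """Doubling the rate constant doubles the rate for any concentrations."""
    species = [Species(f"S{i}") for i in range(len(xs))]
    reactants = tuple((f"S{i}", 1) for i in range(len(xs)))
    index = {f"S{i}": i for i in range(len(xs))}
    r1 = Reaction("r", reactants, (), 1.0)
    r2 = Reaction("r", reactants, (), 2.0)
    x = np.array(xs)
    assert massaction_rate(r2, x, index) == pytest.approx(
        2 * massaction_rate(r1, x, index), rel=1e-12
    )
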