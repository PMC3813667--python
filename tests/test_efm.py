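"""Stoichiometric networks, EFM enumeration, and the synergy score."""

from fractions import Fraction

import numpy as np
import pytest

from metaprox import (
    EFMCapError,
    StoichNetwork,
    brute_force_efms,
    build_paired_networks,
    count_efms,
    enumerate_efms,
    make_random_metabolic_network,
    read_network,
    sample_source_network,
    synergy_curve,
    synergy_score,
    write_network,
)


def net_from(text, tmp_path, name="net.txt"):
    path = tmp_path / name
    path.write_text(text)
    return read_network(path)


class TestReadNetwork:
    def test_round_trip(self, tmp_path):
        net = make_random_metabolic_network(
            n_metabolites=10, n_reactions=8, seed=1
        )
        path = tmp_path / "rt.txt"
        write_network(net, path)
        back = read_network(path)
        assert back.reactions == net.reactions
        assert back.reversible == net.reversible
        for a, b in zip(back.coefficients, net.coefficients):
            assert dict(a) == dict(b)

    def test_sign_convention(self, tmp_path):
        net = net_from("r1 : A + B -> C\n", tmp_path)
        assert dict(net.coefficients[0]) == {
            "A": Fraction(-1), "B": Fraction(-1), "C": Fraction(1)
        }

    def test_duplicate_reaction_id(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            net_from("r1 : A -> B\nr1 : B -> C\n", tmp_path)

    def test_empty_reaction(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            net_from("r1 : A -> A\n", tmp_path)

    def test_undeclared_metabolite_with_declaration_block(self, tmp_path):
        with pytest.raises(ValueError, match="undeclared"):
            net_from("metabolites: A B\nr1 : A -> C\n", tmp_path)

    def test_external_header_and_rational_coefficients(self, tmp_path):
        net = net_from("external: A\nr1 : 1/2 A <-> 2 B\n", tmp_path)
        assert net.externals == frozenset({"A"})
        assert net.reversible == (True,)
        assert dict(net.coefficients[0]) == {"A": Fraction(-1, 2), "B": Fraction(2)}


class TestEnumerate:
    def test_linear_chain_single_mode(self, tmp_path):
        net = net_from("external: A C\nr1 : A -> B\nr2 : B -> C\n", tmp_path)
        assert enumerate_efms(net) == [(Fraction(1), Fraction(1))]

    def test_branch_two_modes(self, tmp_path):
        net = net_from(
            "external: A C D\nr1 : A -> B\nr2 : B -> C\nr3 : B -> D\n", tmp_path
        )
        modes = enumerate_efms(net)
        assert len(modes) == 2
        assert set(modes) == {
            (Fraction(1), Fraction(1), Fraction(0)),
            (Fraction(1), Fraction(0), Fraction(1)),
        }

    def test_no_internal_metabolite_one_mode_per_reaction(self, tmp_path):
        net = net_from("external: A B C\nr1 : A -> B\nr2 : B -> C\n", tmp_path)
        assert len(enumerate_efms(net)) == 2

    def test_reversible_reaction_counted_once(self, tmp_path):
        net = net_from("external: A C\nr1 : A <-> B\nr2 : B <-> C\n", tmp_path)
        modes = enumerate_efms(net)
        # one chain mode (canonical orientation), no futile two-cycles
        assert modes == [(Fraction(1), Fraction(1))]

    def test_stoichiometry_ratios_exact(self, tmp_path):
        net = net_from("external: A C\nr1 : A -> 2 B\nr2 : 3 B -> C\n", tmp_path)
        assert enumerate_efms(net) == [(Fraction(1), Fraction(2, 3))]

    def test_cap_exceeded(self):
        net = make_random_metabolic_network(n_metabolites=40, n_reactions=40, seed=0)
        with pytest.raises(EFMCapError):
            enumerate_efms(net, cap=32)

    def test_conservation_and_minimality_on_random_networks(self):
        for seed in range(5):
            net = make_random_metabolic_network(
                n_metabolites=12, n_reactions=12, seed=seed
            )
            modes = enumerate_efms(net)
            internal = net.internal_metabolites()
            for mode in modes:
                for m in internal:
                    balance = sum(
                        cmap.get(m, Fraction(0)) * v
                        for cmap, v in zip(net.coefficients, mode)
                    )
                    assert balance == 0
            supports = [frozenset(j for j, v in enumerate(mode) if v) for mode in modes]
            for i, si in enumerate(supports):
                for j, sj in enumerate(supports):
                    assert i == j or not si < sj


def test_double_description_matches_brute_force():
    """The nullspace sweep and the exhaustive support enumeration agree
    exactly on random small networks."""
    checked = nonzero = 0
    for seed in range(15):
        net = make_random_metabolic_network(
            n_metabolites=10, n_reactions=8, reversible_fraction=0.25, seed=seed
        )
        a = enumerate_efms(net)
        b = brute_force_efms(net)
        assert a == b
        checked += 1
        nonzero += bool(a)
    assert checked == 15
    assert nonzero >= 5  # the comparison must not be vacuous


class TestSampleSource:
    def test_full_coverage_is_identity(self):
        net = make_random_metabolic_network(seed=3)
        assert sample_source_network(net, 1.0, seed=0) is net

    def test_eighty_percent_of_hundred(self):
        net = make_random_metabolic_network(n_metabolites=60, n_reactions=100, seed=2)
        src = sample_source_network(net, 0.8, seed=5)
        assert src.n_reactions == 80
        assert set(src.reactions) <= set(net.reactions)

    def test_same_seed_same_subset(self):
        net = make_random_metabolic_network(seed=4)
        a = sample_source_network(net, 0.6, seed=11)
        b = sample_source_network(net, 0.6, seed=11)
        assert a.reactions == b.reactions


class TestPairedNetworks:
    def test_sizing_algebra_at_jc_02(self):
        net = make_random_metabolic_network(n_metabolites=60, n_reactions=100, seed=1)
        pair = build_paired_networks(net, 0.2, seed=0)
        assert len(pair.shared) == 20
        assert len(pair.private_1) == len(pair.private_2) == 40
        assert pair.c1.n_reactions == pair.c2.n_reactions == 60
        assert pair.per_network_overlap == Fraction(1, 3)
        assert pair.realized_jc == Fraction(1, 5)

    def test_jc_one_reproduces_source(self):
        net = make_random_metabolic_network(n_metabolites=20, n_reactions=20, seed=6)
        pair = build_paired_networks(net, 1.0, seed=0)
        assert sorted(pair.c1.reactions) == sorted(net.reactions)
        assert sorted(pair.c2.reactions) == sorted(net.reactions)

    def test_jc_zero_disjoint_halves(self):
        net = make_random_metabolic_network(n_metabolites=20, n_reactions=20, seed=7)
        pair = build_paired_networks(net, 0.0, seed=0)
        assert len(pair.shared) == 0
        assert len(pair.private_1) == len(pair.private_2) == 10
        assert not set(pair.c1.reactions) & set(pair.c2.reactions)
        assert pair.realized_jc == 0

    def test_parity_adjustment_keeps_private_sets_equal(self):
        net = make_random_metabolic_network(n_metabolites=20, n_reactions=21, seed=8)
        for jc in (0.0, 0.1, 0.33, 0.5, 0.77, 1.0):
            pair = build_paired_networks(net, jc, seed=1)
            assert len(pair.private_1) == len(pair.private_2)
            total = len(pair.shared) + 2 * len(pair.private_1)
            assert total == 21
            # parity bias is at most one reaction beyond plain rounding
            assert abs(len(pair.shared) - round(jc * 21)) <= 1

    def test_private_metabolites_renamed_in_joint(self):
        net = make_random_metabolic_network(n_metabolites=15, n_reactions=16, seed=9)
        pair = build_paired_networks(net, 0.5, seed=3)
        shared_mets = set(pair.c12.metabolites) - {
            m for m in pair.c12.metabolites if m.endswith("|1") or m.endswith("|2")
        }
        side1 = {m[:-2] for m in pair.c12.metabolites if m.endswith("|1")}
        side2 = {m[:-2] for m in pair.c12.metabolites if m.endswith("|2")}
        # a renamed metabolite never coexists with an un-renamed copy of the
        # shared set and both sides stay separated
        assert not (side1 & shared_mets)
        assert not (side2 & shared_mets)


class TestSynergy:
    def test_score_arithmetic(self):
        assert synergy_score(2, 3, 10) == pytest.approx(2.0)
        assert synergy_score(2, 3, 10, mode="relative_increase") == pytest.approx(1.0)
        assert synergy_score(1, 1, 1) == pytest.approx(0.5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            synergy_score(0, 0, 5)

    def test_disjoint_union_identity(self):
        """At Jc = 0 the joint network is a disconnected union: its modes
        are exactly the two constituents' modes, so the ratio score is 1."""
        hits = 0
        for seed in range(4):
            net = make_random_metabolic_network(
                n_metabolites=14, n_reactions=14, seed=seed
            )
            pair = build_paired_networks(net, 0.0, seed=seed + 50)
            e1, e2 = count_efms(pair.c1), count_efms(pair.c2)
            e12 = count_efms(pair.c12)
            assert e12 == e1 + e2
            if e1 + e2 > 0:
                assert synergy_score(e1, e2, e12) == 1.0
                hits += 1
        assert hits >= 1

    def test_identical_pair_scores_half(self):
        net = make_random_metabolic_network(n_metabolites=14, n_reactions=14, seed=2)
        pair = build_paired_networks(net, 1.0, seed=1)
        e1, e2 = count_efms(pair.c1), count_efms(pair.c2)
        e12 = count_efms(pair.c12)
        if e1 + e2:
            assert synergy_score(e1, e2, e12) == pytest.approx(0.5)

    def test_curve_shape_and_determinism(self):
        net = make_random_metabolic_network(seed=1)
        grid = [0.0, 0.5, 1.0]
        a = synergy_curve(net, grid, n_pairs=4, seed=9)
        b = synergy_curve(net, grid, n_pairs=4, seed=9)
        assert [pt.mean for pt in a] == [pt.mean for pt in b]
        assert [pt.target_jc for pt in a] == grid
        assert a[0].mean == pytest.approx(1.0)  # disjoint-union identity
        for pt in a:
            assert len(pt.scores) + pt.n_skipped == 4
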