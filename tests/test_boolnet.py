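"""Dynamics core: trap spaces, perturbations, reprogramming vs. oracles."""

import itertools

import pytest

from regmis import (BooleanNetwork, Const, InterventionSet, Lit, Not, Or, And,
                    Subcube, apply_perturbation,
                    exhaustive_minimal_inactivating_sets,
                    exhaustive_minimal_trap_spaces, minimal_inactivating_sets,
                    minimal_trap_spaces, parse_gpr, prime_implicants,
                    random_boolean_network, write_bnet)


def net(**funcs):
    return BooleanNetwork({k: parse_gpr(v) for k, v in funcs.items()})


class TestMinimalTrapSpaces:
    def test_constant_network_single_fixed_point(self):
        bn = BooleanNetwork({"a": Const(1)})
        assert minimal_trap_spaces(bn) == {Subcube({"a": 1})}

    def test_toggle_switch_two_attractors(self):
        bn = net(r1="not r2", r2="not r1")
        assert minimal_trap_spaces(bn) == {Subcube({"r1": 1, "r2": 0}),
                                           Subcube({"r1": 0, "r2": 1})}

    def test_cyclic_egpr_fixture(self, toggle_net):
        expected = {Subcube({"Rx": 1, "g1": 1, "r1": 1, "r2": 0}),
                    Subcube({"Rx": 0, "g1": 0, "r1": 0, "r2": 1})}
        assert minimal_trap_spaces(toggle_net.bn) == expected

    def test_negative_self_loop_leaves_node_unfixed(self):
        bn = net(a="not a")
        assert minimal_trap_spaces(bn) == {Subcube({})}

    @pytest.mark.parametrize("seed", range(1, 26))
    def test_oracle_equivalence_random_networks(self, seed):
        """Supported-set search equals the 3^n subcube scan."""
        bn = random_boolean_network(7, 2, seed)
        assert minimal_trap_spaces(bn) == exhaustive_minimal_trap_spaces(bn)

    def test_percolating_oracle_agrees_with_plain_oracle(self):
        for seed in range(1, 11):
            bn = random_boolean_network(6, 2, seed)
            assert (exhaustive_minimal_trap_spaces(bn, percolate=True)
                    == exhaustive_minimal_trap_spaces(bn, percolate=False))


class TestPrimeImplicants:
    @pytest.mark.parametrize("seed", range(1, 16))
    def test_pi_definition_holds(self, seed):
        """Each PI forces the function; dropping any literal breaks it; all
        minterms are covered."""
        bn = random_boolean_network(5, 3, seed)
        for x in bn.nodes:
            expr = bn.f[x]
            vs = expr.variables()
            pis = prime_implicants(expr)
            for pi in pis:
                envs = [dict(zip(vs, bits)) for bits in
                        itertools.product((0, 1), repeat=len(vs))]
                forced = [e for e in envs if all(e[g] == v for g, v in pi.items())]
                assert all(expr.evaluate(e) for e in forced)
                for drop in pi:
                    sub = {g: v for g, v in pi.items() if g != drop}
                    weaker = [e for e in envs if all(e[g] == v for g, v in sub.items())]
                    assert not all(expr.evaluate(e) for e in weaker)
            for e in (dict(zip(vs, bits)) for bits in
                      itertools.product((0, 1), repeat=len(vs))):
                if expr.evaluate(e):
                    assert any(all(e[g] == v for g, v in pi.items()) for pi in pis)


class TestApplyPerturbation:
    def test_empty_perturbation_is_identity(self, toggle_net):
        assert apply_perturbation(toggle_net.bn, InterventionSet()) == toggle_net.bn

    def test_knockout_pins_function_and_silences_marker(self, toggle_net):
        pbn = apply_perturbation(toggle_net.bn, InterventionSet(KO=["g1"]))
        assert pbn.f["g1"] == Const(0)
        assert all(ts.get("Rx") == 0 for ts in exhaustive_minimal_trap_spaces(pbn))

    def test_ko_ki_overlap_rejected(self):
        with pytest.raises(ValueError):
            InterventionSet(KO=["g1"], KI=["g1"])

    def test_unknown_gene_rejected(self, toggle_net):
        with pytest.raises(ValueError, match="zz"):
            apply_perturbation(toggle_net.bn, InterventionSet(KO=["zz"]))


class TestMinimalInactivatingSets:
    def test_and_gpr_either_conjunct(self):
        bn = net(Rx="g1 and g2", g1="g1", g2="g2")
        assert minimal_inactivating_sets(bn, "Rx", kmax=2) == [
            InterventionSet(KO=["g1"]), InterventionSet(KO=["g2"])]

    def test_or_gpr_needs_both(self):
        bn = net(Rx="g1 or g2", g1="g1", g2="g2")
        assert minimal_inactivating_sets(bn, "Rx", kmax=2) == [
            InterventionSet(KO=["g1", "g2"])]

    def test_toggle_fixture_three_singletons(self, toggle_net):
        assert minimal_inactivating_sets(toggle_net.bn, "Rx", kmax=1) == [
            InterventionSet(KI=["r2"]), InterventionSet(KO=["g1"]),
            InterventionSet(KO=["r1"])]

    def test_missing_marker_rejected(self, toggle_net):
        with pytest.raises(ValueError):
            minimal_inactivating_sets(toggle_net.bn, "nope")

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_oracle_equivalence_random_networks(self, seed):
        bn = random_boolean_network(6, 2, seed)
        marker = bn.nodes[0]
        assert (minimal_inactivating_sets(bn, marker, kmax=2)
                == exhaustive_minimal_inactivating_sets(bn, marker, kmax=2))

    def test_antichain_property(self, toggle_net):
        sols = minimal_inactivating_sets(toggle_net.bn, "Rx", kmax=3)
        for a in sols:
            for b in sols:
                assert not (a != b and a.issubset(b))

    def test_unread_node_leaves_results_unchanged(self, toggle_net):
        f = dict(toggle_net.bn.f)
        f["spectator"] = Lit("spectator")
        bigger = BooleanNetwork(f)
        base = minimal_inactivating_sets(toggle_net.bn, "Rx", kmax=2)
        extended = minimal_inactivating_sets(bigger, "Rx", kmax=2,
                                             candidates=toggle_net.bn.nodes)
        assert base == extended

    def test_acyclic_ko_sets_are_hitting_sets_of_prime_implicants(self):
        """On an acyclic network, knockout-only solutions equal the minimal
        hitting sets of the propagated marker function's prime implicants
        (computed here by independent brute force over subcubes)."""
        bn = net(Rx="(a and b) or c", a="a", b="b", c="c")
        sols = [s for s in minimal_inactivating_sets(bn, "Rx", kmax=3) if not s.KI]
        ko_sets = sorted(tuple(sorted(s.KO)) for s in sols)

        # independent: enumerate implicants of the propagated function by
        # brute force, keep the prime ones, then minimal hitting sets
        expr = bn.f["Rx"]
        vs = expr.variables()
        implicants = []
        for cell in itertools.product((None, 0, 1), repeat=len(vs)):
            fixed = {g: v for g, v in zip(vs, cell) if v is not None}
            if not fixed:
                continue
            envs = [dict(zip(vs, bits)) for bits in
                    itertools.product((0, 1), repeat=len(vs))]
            if all(expr.evaluate(e) for e in envs
                   if all(e[g] == v for g, v in fixed.items())):
                implicants.append(fixed)
        primes = [im for im in implicants
                  if not any(set(o.items()) < set(im.items()) for o in implicants)]
        pos_primes = [set(im) for im in primes if all(v == 1 for v in im.values())]
        hitting = []
        for size in range(1, 4):
            for combo in itertools.combinations(vs, size):
                s = set(combo)
                if all(s & p for p in pos_primes) and \
                        not any(set(h) < s for h in hitting):
                    hitting.append(tuple(sorted(s)))
        assert ko_sets == sorted(hitting)


def test_bnet_export_format(toggle_net, tmp_path):
    p = tmp_path / "net.bnet"
    write_bnet(toggle_net.bn, p)
    lines = p.read_text().splitlines()
    assert lines[0] == "targets, factors"
    assert "r1, !r2" in lines
    assert "Rx, g1" in lines
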