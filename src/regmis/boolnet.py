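"""Boolean-network dynamics: trap spaces, perturbations, reprogramming.

Attractors are identified with *minimal trap spaces*: subcubes of the state
space closed under the update functions and containing no smaller closed
subcube.  Under permissive update semantics these coincide with the
attractors of the network, which makes the analysis independent of the
update scheme and amenable to exact computation.

The production routine :func:`minimal_trap_spaces` characterizes trap spaces
as *supported, consistent literal sets*: a subcube fixing the literals ``L``
is closed iff every literal ``x=v`` in ``L`` is witnessed by a prime
implicant of ``f_x`` (for ``v=1``) or of ``NOT f_x`` (for ``v=0``) whose
literals all lie in ``L``.  Minimal trap spaces are then exactly the maximal
supported consistent literal sets, enumerated here by a pruned depth-first
search over node decisions.  Exhaustive ``3^n``-subcube oracles are provided
alongside for validation; they share no code path with the production
routines beyond expression evaluation.

Free inputs are modeled as self-referential update functions (``f_x = x``)
so a trap space may either leave them unfixed or pin them to a constant;
minimal trap spaces always pin them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model_io import And, BooleanExpr, Const, Lit, Not, Or

__all__ = [
    "BooleanNetwork", "Subcube", "InterventionSet",
    "minimal_trap_spaces", "exhaustive_minimal_trap_spaces",
    "apply_perturbation", "marker_always_zero",
    "minimal_inactivating_sets", "exhaustive_minimal_inactivating_sets",
    "prime_implicants", "write_bnet",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """Named Boolean network; node order is canonical (sorted).

    ``f`` maps every node to its update expression; variables of every
    expression must themselves be nodes.  A free input is encoded as
    ``f[x] = Lit(x)``.
    """

    nodes: tuple[str, ...]
    f: Mapping[str, BooleanExpr]

    def __init__(self, f: Mapping[str, BooleanExpr]):
        object.__setattr__(self, "nodes", tuple(sorted(f)))
        object.__setattr__(self, "f", dict(f))
        nodeset = set(self.nodes)
        for x, expr in self.f.items():
            extra = set(expr.variables()) - nodeset
            if extra:
                raise ValueError(f"function of {x!r} reads non-node(s) {sorted(extra)}")

    def is_input(self, x: str) -> bool:
        return self.f[x] == Lit(x)

    def __hash__(self):
        return hash((self.nodes, tuple(self.f[x] for x in self.nodes)))


@dataclass(frozen=True, order=True)
class Subcube:
    """Partial assignment of nodes; unmentioned nodes are free.

    A trap-space subcube is closed: no fixed node's function can evaluate to
    the opposite value anywhere inside the subcube.
    """

    fixed: tuple[tuple[str, int], ...]

    def __init__(self, assignment: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = dict(assignment)
        for v in items.values():
            if v not in (0, 1):
                raise ValueError("subcube values must be 0 or 1")
        object.__setattr__(self, "fixed", tuple(sorted(items.items())))

    def get(self, node: str):
        return dict(self.fixed).get(node)

    def as_dict(self) -> dict[str, int]:
        return dict(self.fixed)

    def __len__(self):
        return len(self.fixed)

    def __repr__(self):
        inner = ", ".join(f"{k}={v}" for k, v in self.fixed)
        return f"Subcube({inner})"


@dataclass(frozen=True)
class InterventionSet:
    """Signed gene perturbation: KO genes pinned to 0, KI genes pinned to 1."""

    KO: frozenset[str] = frozenset()
    KI: frozenset[str] = frozenset()

    def __init__(self, KO: Iterable[str] = (), KI: Iterable[str] = ()):
        KO, KI = frozenset(KO), frozenset(KI)
        if KO & KI:
            raise ValueError(f"gene(s) {sorted(KO & KI)} in both KO and KI")
        object.__setattr__(self, "KO", KO)
        object.__setattr__(self, "KI", KI)

    def __len__(self):
        return len(self.KO) + len(self.KI)

    def genes(self) -> frozenset[str]:
        return self.KO | self.KI

    def issubset(self, other: "InterventionSet") -> bool:
        return self.KO <= other.KO and self.KI <= other.KI

    def sort_key(self):
        return (len(self), tuple(sorted(self.KO)), tuple(sorted(self.KI)))

    def __repr__(self):
        parts = [f"{g}-" for g in sorted(self.KO)] + [f"{g}+" for g in sorted(self.KI)]
        return "{" + ", ".join(parts) + "}"


# ---------------------------------------------------------------------------
# Expression helpers
# ---------------------------------------------------------------------------

def _substitute_consts(expr: BooleanExpr, known: Mapping[str, int]) -> BooleanExpr:
    """Substitute constants and propagate them syntactically."""
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Lit):
        return Const(known[expr.name]) if expr.name in known else expr
    if isinstance(expr, Not):
        inner = _substitute_consts(expr.arg, known)
        if isinstance(inner, Const):
            return Const(1 - inner.value)
        return Not(inner)
    args = [_substitute_consts(a, known) for a in expr.args]
    if isinstance(expr, And):
        if any(isinstance(a, Const) and a.value == 0 for a in args):
            return Const(0)
        args = [a for a in args if not isinstance(a, Const)]
        if not args:
            return Const(1)
        return args[0] if len(args) == 1 else And(*args)
    if any(isinstance(a, Const) and a.value == 1 for a in args):
        return Const(1)
    args = [a for a in args if not isinstance(a, Const)]
    if not args:
        return Const(0)
    return args[0] if len(args) == 1 else Or(*args)


def prime_implicants(expr: BooleanExpr, variables: Sequence[str] | None = None
                     ) -> list[dict[str, int]]:
    """All prime implicants of ``expr`` via Quine-McCluskey.

    Each implicant is a partial assignment forcing the expression to 1; the
    tautology yields the single empty implicant, the contradiction none.
    Supports are small here (regulator in-degrees), so table enumeration over
    ``2^k`` assignments is cheap.
    """
    if variables is None:
        variables = expr.variables()
    variables = tuple(variables)
    k = len(variables)
    minterms = []
    for bits in range(1 << k):
        env = {variables[i]: (bits >> i) & 1 for i in range(k)}
        if expr.evaluate(env):
            minterms.append(bits)
    if not minterms:
        return []
    if len(minterms) == 1 << k:
        return [{}]
    # implicant = (care_mask, values); merge pairs differing in one cared bit
    current = {(((1 << k) - 1), m) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        cur = list(current)
        by_mask: dict[int, list[int]] = {}
        for mask, vals in cur:
            by_mask.setdefault(mask, []).append(vals)
        for mask, vals_list in by_mask.items():
            vset = set(vals_list)
            for vals in vals_list:
                for i in range(k):
                    bit = 1 << i
                    if not (mask & bit):
                        continue
                    if (vals ^ bit) in vset:
                        merged.add((mask & ~bit, vals & ~bit))
                        used.add((mask, vals))
                        used.add((mask, vals ^ bit))
        primes.update(current - used)
        current = merged
    out = []
    for mask, vals in primes:
        out.append({variables[i]: (vals >> i) & 1 for i in range(k) if mask & (1 << i)})
    # deterministic order: fewest literals first, then lexicographic
    out.sort(key=lambda d: (len(d), sorted(d.items())))
    return out


def percolate_constants(bn: BooleanNetwork) -> tuple[dict[str, int], dict[str, BooleanExpr]]:
    """Fixpoint of syntactic constant propagation.

    Returns the forced node values and the substituted update functions of
    the remaining nodes.  A node whose update function is constant is fixed
    in every minimal trap space, so this preprocessing is exact.
    """
    known: dict[str, int] = {}
    funcs = dict(bn.f)
    changed = True
    while changed:
        changed = False
        for x in list(funcs):
            expr = _substitute_consts(funcs[x], known)
            funcs[x] = expr
            if isinstance(expr, Const):
                known[x] = expr.value
                del funcs[x]
                changed = True
    return known, funcs


# ---------------------------------------------------------------------------
# Minimal trap spaces (production: supported-literal-set search)
# ---------------------------------------------------------------------------

def _literal_bitmask(order: dict[str, int], literals: Iterable[tuple[str, int]]) -> tuple[int, int]:
    mask = vals = 0
    for node, v in literals:
        bit = 1 << order[node]
        mask |= bit
        if v:
            vals |= bit
    return mask, vals


def _filter_maximal(cands: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep literal sets with no strict superset among the candidates."""
    cands = sorted(set(cands), key=lambda mv: -bin(mv[0]).count("1"))
    kept: list[tuple[int, int]] = []
    for mask, vals in cands:
        dominated = False
        for km, kv in kept:
            if km & mask == mask and kv & mask == vals & mask and km != mask:
                dominated = True
                break
        if not dominated:
            kept.append((mask, vals))
    return kept


def minimal_trap_spaces(bn: BooleanNetwork) -> frozenset[Subcube]:
    """Exactly the inclusion-minimal trap spaces of ``bn``.

    Constants are percolated first; remaining literals are enumerated by a
    depth-first search over per-node decisions (fix to 0, fix to 1, or leave
    free) pruned by prime-implicant supportability, then filtered to maximal
    supported sets.  Validated against :func:`exhaustive_minimal_trap_spaces`
    in the test suite.
    """
    known, funcs = percolate_constants(bn)
    nodes = sorted(funcs)
    n = len(nodes)
    if n == 0:
        return frozenset({Subcube(known)})
    order = {x: i for i, x in enumerate(nodes)}

    # pis[x][v] = prime implicants witnessing literal x=v
    pis: dict[str, dict[int, list[dict[str, int]]]] = {}
    self_supported: dict[str, list[int]] = {}
    for x in nodes:
        pos = prime_implicants(funcs[x])
        neg = prime_implicants(Not(funcs[x]))
        pis[x] = {1: pos, 0: neg}
        self_supported[x] = [v for v in (0, 1)
                             if any(set(pi) <= {x} and pi.get(x, v) == v for pi in pis[x][v])]

    supported_sets: list[tuple[int, int]] = []
    decision: dict[str, int | None] = {}

    def feasible(x: str, v: int) -> bool:
        # some witness PI must avoid nodes decided free or decided opposite
        for pi in pis[x][v]:
            ok = True
            for g, gv in pi.items():
                if g == x:
                    if gv != v:
                        ok = False
                        break
                    continue
                d = decision.get(g, "undecided")
                if d is None or (d != "undecided" and d != gv):
                    ok = False
                    break
            if ok:
                return True
        return False

    def leaf_supported() -> bool:
        for x, v in decision.items():
            if v is None:
                continue
            if not any(all(decision.get(g) == gv for g, gv in pi.items())
                       for pi in pis[x][v]):
                return False
        return True

    def dfs(i: int) -> None:
        if i == n:
            if leaf_supported():
                lits = [(x, v) for x, v in decision.items() if v is not None]
                supported_sets.append(_literal_bitmask(order, lits))
            return
        x = nodes[i]
        for v in (0, 1):
            if feasible(x, v):
                decision[x] = v
                dfs(i + 1)
        # leaving x free can never be maximal when x supports its own literal
        if not self_supported[x]:
            decision[x] = None
            dfs(i + 1)
        decision.pop(x, None)

    dfs(0)
    out = set()
    for mask, vals in _filter_maximal(supported_sets):
        assign = dict(known)
        for i, x in enumerate(nodes):
            if mask & (1 << i):
                assign[x] = (vals >> i) & 1
        out.add(Subcube(assign))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Exhaustive oracle: 3^n subcube scan
# ---------------------------------------------------------------------------

def exhaustive_minimal_trap_spaces(bn: BooleanNetwork, percolate: bool = False
                                   ) -> frozenset[Subcube]:
    """Brute-force oracle: scan all ``3^n`` subcubes for closure, keep minimal.

    With ``percolate=True`` constants are propagated first (exact, see
    :func:`percolate_constants`) so the scan runs over the reduced network;
    used where whole perturbation corpora are scanned.
    """
    if percolate:
        known, funcs = percolate_constants(bn)
    else:
        known, funcs = {}, dict(bn.f)
    nodes = sorted(funcs)
    n = len(nodes)
    order = {x: i for i, x in enumerate(nodes)}

    supports = {}
    tables = {}
    for x in nodes:
        sup = funcs[x].variables()
        supports[x] = sup
        tab = []
        for bits in range(1 << len(sup)):
            env = {sup[i]: (bits >> i) & 1 for i in range(len(sup))}
            tab.append(funcs[x].evaluate(env))
        tables[x] = tab

    closed: list[tuple[int, int]] = []
    for cell in itertools.product((None, 0, 1), repeat=n):
        ok = True
        for i, v in enumerate(cell):
            if v is None:
                continue
            x = nodes[i]
            sup = supports[x]
            tab = tables[x]
            # every completion of the support inside the subcube must give v
            free_positions = [j for j, g in enumerate(sup) if cell[order[g]] is None]
            base = 0
            for j, g in enumerate(sup):
                gv = cell[order[g]]
                if gv:
                    base |= 1 << j
            violated = False
            for combo in range(1 << len(free_positions)):
                bits = base
                for t, j in enumerate(free_positions):
                    if (combo >> t) & 1:
                        bits |= 1 << j
                if tab[bits] != v:
                    violated = True
                    break
            if violated:
                ok = False
                break
        if ok:
            closed.append(_literal_bitmask(order, ((nodes[i], v) for i, v in enumerate(cell)
                                                   if v is not None)))

    out = set()
    for mask, vals in _filter_maximal(closed):
        assign = dict(known)
        for i, x in enumerate(nodes):
            if mask & (1 << i):
                assign[x] = (vals >> i) & 1
        out.add(Subcube(assign))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Perturbations and marker reprogramming
# ---------------------------------------------------------------------------

def apply_perturbation(bn: BooleanNetwork, p: InterventionSet) -> BooleanNetwork:
    """Pin KO nodes to ``0`` and KI nodes to ``1``; other functions untouched."""
    missing = p.genes() - set(bn.nodes)
    if missing:
        raise ValueError(f"perturbed gene(s) {sorted(missing)} not in network")
    f = dict(bn.f)
    for g in p.KO:
        f[g] = Const(0)
    for g in p.KI:
        f[g] = Const(1)
    return BooleanNetwork(f)


def marker_always_zero(bn: BooleanNetwork, marker: str) -> bool:
    """True iff every minimal trap space fixes ``marker`` to 0.

    A trap space leaving the marker unfixed counts as *not* inactive.  The
    percolation fast path settles most perturbed networks without trap-space
    enumeration.
    """
    known, _funcs = percolate_constants(bn)
    if marker in known:
        return known[marker] == 0
    return all(ts.get(marker) == 0 for ts in minimal_trap_spaces(bn))


def _signed_subsets(candidates: Sequence[str], size: int):
    for combo in itertools.combinations(candidates, size):
        for signs in itertools.product((0, 1), repeat=size):
            yield InterventionSet(
                KO=[g for g, s in zip(combo, signs) if s == 0],
                KI=[g for g, s in zip(combo, signs) if s == 1])


def minimal_inactivating_sets(bn: BooleanNetwork, marker: str, kmax: int = 3,
                              candidates: Sequence[str] | None = None
                              ) -> list[InterventionSet]:
    """All inclusion-minimal interventions of size <= kmax silencing the marker.

    Breadth-first over signed gene subsets by cardinality, skipping supersets
    of recorded solutions.  Every strict subset of a hit was already tested
    (and failed) at a smaller cardinality, so recorded hits are exactly the
    inclusion-minimal solutions — no monotonicity assumption is needed.
    If the unperturbed network already silences the marker the empty
    intervention is returned as the unique minimal solution.
    """
    if marker not in bn.nodes:
        raise ValueError(f"marker {marker!r} not in network")
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if candidates is None:
        candidates = [x for x in bn.nodes if x != marker]
    candidates = sorted(set(candidates) - {marker})
    if marker_always_zero(bn, marker):
        return [InterventionSet()]
    found: list[InterventionSet] = []
    for size in range(1, kmax + 1):
        for iv in _signed_subsets(candidates, size):
            if any(sol.issubset(iv) for sol in found):
                continue
            if marker_always_zero(apply_perturbation(bn, iv), marker):
                found.append(iv)
    return sorted(found, key=InterventionSet.sort_key)


def exhaustive_minimal_inactivating_sets(bn: BooleanNetwork, marker: str, kmax: int = 3
                                         ) -> list[InterventionSet]:
    """Oracle: test *every* signed subset with brute-force trap spaces.

    No superset skipping — all subsets up to ``kmax`` are checked and
    non-minimal solutions are discarded afterwards; the trap-space check is
    the exhaustive subcube scan (with exact constant percolation so whole
    perturbation corpora stay tractable).
    """
    candidates = sorted(set(bn.nodes) - {marker})

    def inactive(p: InterventionSet) -> bool:
        pbn = apply_perturbation(bn, p)
        return all(ts.get(marker) == 0
                   for ts in exhaustive_minimal_trap_spaces(pbn, percolate=True))

    if inactive(InterventionSet()):
        return [InterventionSet()]
    hits = [iv for size in range(1, kmax + 1)
            for iv in _signed_subsets(candidates, size) if inactive(iv)]
    minimal = [iv for iv in hits
               if not any(other.issubset(iv) and other != iv for other in hits)]
    return sorted(minimal, key=InterventionSet.sort_key)


# ---------------------------------------------------------------------------
# Interchange
# ---------------------------------------------------------------------------

def write_bnet(bn: BooleanNetwork, path: str | Path) -> None:
    """Write the ``.bnet`` text format (node, comma, factor expression)."""
    with Path(path).open("w") as fh:
        fh.write("targets, factors\n")
        for x in bn.nodes:
            expr = bn.f[x].render()
            expr = expr.replace(" and ", " & ").replace(" or ", " | ").replace("not ", "!")
            fh.write(f"{x}, {expr}\n")
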