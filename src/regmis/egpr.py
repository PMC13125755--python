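"""Extended GPR construction: layered expansion of regulation into GPR logic.

Each reaction's GPR rule is grown into a per-reaction Boolean network (the
*eGPR*): the reaction marker node computes the GPR over its layer-0
metabolic genes; direct regulators of those genes are wired in at layer 1,
their regulators at layer 2, and so on up to a configurable depth.  Cycles —
including self-loops — are kept, which is the point of the construction:
regulatory feedback is modeled rather than linearized away.

Wiring a gene can make the network inconsistent (no attractor leaves the
reaction attainable), so after every per-gene expansion a reachability check
runs on the current network; a failing expansion is reverted and the gene
stays a free input.  Genes within a layer are processed in lexicographic
order, making the construction deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .boolnet import BooleanNetwork, minimal_trap_spaces, percolate_constants
from .model_io import And, BooleanExpr, Const, Lit, Not, Or, MetabolicModel, RegulatoryNetwork

logger = logging.getLogger("regmis")

__all__ = ["LayerConfig", "EGPRNetwork", "combine_regulators",
           "expand_reaction", "check_target_reachable"]


@dataclass(frozen=True)
class LayerConfig:
    """Expansion depth and reachability semantics.

    ``n_layers`` is the number of regulatory layers wired in (0 keeps the
    pure GPR).  ``strict_reachability`` selects what counts as "the reaction
    is attainable" in some attractor: by default a minimal trap space that
    leaves the marker unfixed (or fixes it to 1) suffices; the strict
    reading requires a trap space fixing the marker to 1.
    """

    n_layers: int = 1
    strict_reachability: bool = False

    def __post_init__(self):
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")


@dataclass
class EGPRNetwork:
    """Per-reaction Boolean network plus bookkeeping.

    ``marker`` is the reaction node; ``layer`` tags each node with the
    expansion step that introduced it (0 = metabolic gene of the GPR);
    ``log`` records per-gene expansion events as (gene, layer, kept/reverted).
    """

    bn: BooleanNetwork
    marker: str
    layer: dict[str, int]
    log: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def nodes(self):
        return self.bn.nodes


def combine_regulators(activators: set[str] | list[str],
                       repressors: set[str] | list[str]) -> BooleanExpr:
    """Default regulator combination: OR(activators) AND NOT OR(repressors).

    A threshold-free convention: the gene is on when at least one activator
    is on and no repressor is.  With only repressors the gene defaults to on
    in their absence; with only activators it simply follows them.
    """
    acts = sorted(set(activators))
    reps = sorted(set(repressors))
    if not acts and not reps:
        raise ValueError("at least one regulator required")
    act_expr = None
    if acts:
        act_expr = Lit(acts[0]) if len(acts) == 1 else Or(*[Lit(a) for a in acts])
    rep_expr = None
    if reps:
        rep_expr = Not(Lit(reps[0]) if len(reps) == 1 else Or(*[Lit(r) for r in reps]))
    if act_expr is None:
        return rep_expr
    if rep_expr is None:
        return act_expr
    return And(act_expr, rep_expr)


def check_target_reachable(bn: BooleanNetwork, marker: str,
                           strict: bool = False) -> bool:
    """Does some attractor leave the reaction attainable?

    True iff a minimal trap space of the unperturbed network does not fix
    the marker to 0 (lenient default) or fixes it to 1 (``strict``).
    """
    if marker not in bn.nodes:
        raise ValueError(f"marker {marker!r} not in network")
    known, _ = percolate_constants(bn)
    if marker in known:
        return known[marker] == 1
    spaces = minimal_trap_spaces(bn)
    if strict:
        return any(ts.get(marker) == 1 for ts in spaces)
    return any(ts.get(marker) != 0 for ts in spaces)


def expand_reaction(model: MetabolicModel, regnet: RegulatoryNetwork,
                    reaction: str, layers: LayerConfig) -> EGPRNetwork:
    """Build the eGPR network of one reaction by layered expansion.

    Layer-0 genes are those of the GPR; at layer ``k`` every gene introduced
    at layer ``k-1`` that has regulators acquires the combined update rule,
    its unseen regulators entering as free inputs tagged layer ``k``.
    Regulators already present are wired back, closing cycles.  Nodes
    introduced at the final layer are additionally wired when *all* their
    regulators are already in the network (pure back-wiring, no horizon
    extension); genes with regulators beyond the horizon remain free inputs.

    After each per-gene wiring the reachability check runs; on failure the
    gene's wiring is reverted (it stays an input), regulator nodes added
    solely for it are removed, and the event is logged.
    """
    if reaction not in model.reactions:
        raise ValueError(f"reaction {reaction!r} not in model")
    gpr = model.gpr_of(reaction)
    if isinstance(gpr, Const):
        raise ValueError(f"reaction {reaction!r} has a constant GPR; nothing to expand")

    marker = reaction
    genes0 = list(gpr.variables())
    if marker in genes0:
        raise ValueError(f"reaction id {reaction!r} collides with a gene id in its GPR")
    f: dict[str, BooleanExpr] = {marker: gpr}
    layer: dict[str, int] = {marker: 0}
    for g in genes0:
        f[g] = Lit(g)
        layer[g] = 0
    log: list[tuple[str, int, str]] = []

    def try_wire(gene: str, expr: BooleanExpr, new_nodes: list[str], k: int) -> bool:
        """Wire ``gene``, check reachability, revert on failure."""
        f[gene] = expr
        for nn in new_nodes:
            f[nn] = Lit(nn)
            layer[nn] = k
        if check_target_reachable(BooleanNetwork(f), marker,
                                  strict=layers.strict_reachability):
            log.append((gene, k, "kept"))
            return True
        f[gene] = Lit(gene)
        for nn in new_nodes:
            del f[nn]
            del layer[nn]
        log.append((gene, k, "reverted"))
        logger.info("expansion of %s at layer %d reverted for reaction %s "
                    "(target unreachable)", gene, k, reaction)
        return False

    frontier = sorted(genes0)
    for k in range(1, layers.n_layers + 1):
        added_this_layer: list[str] = []
        for gene in frontier:
            acts, reps = regnet.regulators_of(gene)
            if not acts and not reps:
                continue
            new_nodes = [r for r in sorted(set(acts) | set(reps)) if r not in f]
            if try_wire(gene, combine_regulators(acts, reps), new_nodes, k):
                added_this_layer.extend(n for n in new_nodes if n in f)
        frontier = sorted(added_this_layer)

    # back-wiring pass: final-layer inputs whose regulators are all present
    for gene in frontier if layers.n_layers > 0 else []:
        acts, reps = regnet.regulators_of(gene)
        if not acts and not reps:
            continue
        if all(r in f for r in set(acts) | set(reps)):
            try_wire(gene, combine_regulators(acts, reps), [], layers.n_layers)

    return EGPRNetwork(bn=BooleanNetwork(f), marker=marker, layer=layer, log=log)
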