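"""Assemble the per-reaction intervention catalogue (GDict) and G/F matrices.

For every reaction with a gene association, the eGPR network is built and
the minimal marker-inactivating intervention sets are enumerated; each
becomes an intervention row (knockout set K, knock-in set N).  The rows per
reaction form an antichain.  For the MILP stage the catalogue is rendered as
two binary matrices over a gene order: G marks knockouts, F knock-ins.

Reactions are processed independently, so the build parallelizes over a
worker pool; results are merged in reaction order and are identical for any
worker count.
"""

from __future__ import annotations

import logging
import multiprocessing
from dataclasses import dataclass, field

import numpy as np

from .boolnet import InterventionSet, minimal_inactivating_sets
from .egpr import LayerConfig, check_target_reachable, expand_reaction
from .model_io import Const, MetabolicModel, RegulatoryNetwork

logger = logging.getLogger("regmis")

__all__ = ["InterventionRow", "GDict", "GFMatrices",
           "build_gdict", "gdict_to_matrices"]


@dataclass(frozen=True)
class InterventionRow:
    """One minimal way to genetically inactivate a reaction."""

    K: frozenset[str]
    N: frozenset[str]
    reaction: str

    def __post_init__(self):
        if self.K & self.N:
            raise ValueError(f"gene(s) {sorted(self.K & self.N)} in both K and N")
        if not (self.K | self.N):
            raise ValueError("empty intervention row")

    def sort_key(self):
        return (len(self.K) + len(self.N), tuple(sorted(self.K)), tuple(sorted(self.N)))


@dataclass
class GDict:
    """Reaction id -> ordered antichain of intervention rows, plus provenance."""

    rows: dict[str, list[InterventionRow]]
    provenance: dict = field(default_factory=dict)

    def genes(self) -> list[str]:
        out: set[str] = set()
        for rws in self.rows.values():
            for row in rws:
                out |= row.K | row.N
        return sorted(out)

    def n_rows(self) -> int:
        return sum(len(r) for r in self.rows.values())


@dataclass
class GFMatrices:
    """Binary constraint matrices: G (knockouts) and F (knock-ins).

    One row per intervention row, ordered by (reaction order, canonical row
    order); columns follow ``genes``.
    """

    G: np.ndarray
    F: np.ndarray
    genes: list[str]
    row_reactions: list[str]


def _rows_for_reaction(args) -> tuple[str, list[InterventionRow], list[tuple[str, int, str]]]:
    model, regnet, rid, layers, kmax = args
    net = expand_reaction(model, regnet, rid, layers)
    if not check_target_reachable(net.bn, net.marker, strict=layers.strict_reachability):
        logger.info("reaction %s: marker unreachable even unperturbed; no rows", rid)
        return rid, [], net.log
    sets = minimal_inactivating_sets(net.bn, net.marker, kmax=kmax)
    rows = [InterventionRow(K=s.KO, N=s.KI, reaction=rid) for s in sets if len(s) > 0]
    return rid, rows, net.log


def build_gdict(model: MetabolicModel, regnet: RegulatoryNetwork,
                layers: LayerConfig, kmax: int = 3, workers: int = 1) -> GDict:
    """Build the GDict for every reaction with a non-constant GPR.

    Reactions without a gene association can never be blocked genetically
    and produce no rows.  Reactions whose marker is unreachable even in the
    unperturbed eGPR get an empty row list and a log entry.  The result is
    deterministic and identical for any ``workers`` count.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    gpr_reactions = [rid for rid in model.reactions
                     if not isinstance(model.gpr_of(rid), Const)]
    tasks = [(model, regnet, rid, layers, kmax) for rid in gpr_reactions]
    if workers == 1 or len(tasks) <= 1:
        results = [_rows_for_reaction(t) for t in tasks]
    else:
        ctx = multiprocessing.get_context("fork" if "fork" in
                                          multiprocessing.get_all_start_methods() else "spawn")
        with ctx.Pool(workers) as pool:
            results = pool.map(_rows_for_reaction, tasks)
    rows = {rid: rws for rid, rws, _log in results}
    expansion_log = {rid: log for rid, _rws, log in results}
    gd = GDict(rows={rid: rows[rid] for rid in gpr_reactions},
               provenance={"layers": layers.n_layers, "kmax": kmax,
                           "model": model.id, "target": model.target})
    gd.expansion_log = expansion_log  # per-reaction (gene, layer, kept/reverted)
    return gd


def gdict_to_matrices(gdict: GDict, gene_order: list[str]) -> GFMatrices:
    """Render the GDict rows as binary G/F matrices over ``gene_order``."""
    gidx = {g: i for i, g in enumerate(gene_order)}
    unknown = set(gdict.genes()) - set(gene_order)
    if unknown:
        raise ValueError(f"gene(s) {sorted(unknown)} missing from gene_order")
    n = gdict.n_rows()
    G = np.zeros((n, len(gene_order)), dtype=int)
    F = np.zeros((n, len(gene_order)), dtype=int)
    row_reactions = []
    i = 0
    for rid, rws in gdict.rows.items():
        for row in sorted(rws, key=InterventionRow.sort_key):
            for g in row.K:
                G[i, gidx[g]] = 1
            for g in row.N:
                F[i, gidx[g]] = 1
            row_reactions.append(rid)
            i += 1
    return GFMatrices(G=G, F=F, genes=list(gene_order), row_reactions=row_reactions)
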