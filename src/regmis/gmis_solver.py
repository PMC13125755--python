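"""Enumeration of genetic Minimal Intervention Sets (gMISs).

A gMIS is an inclusion-minimal set of signed gene interventions (knockouts
``g-``, knock-ins ``g+``) whose induced reaction blockings make the target
reaction infeasible under steady-state flux balance: the LP

    max  v_target   s.t.  S v = 0,  lb <= v <= ub,  v_r = 0 for blocked r

has optimum at (numerically) zero.  A reaction is blocked when some row
(K, N) of its GDict entry fires, i.e. K is knocked out and N knocked in.

Enumeration is a lazy-cut loop over a master MILP with one binary selection
variable per candidate intervention (``g-`` for genes in any K, ``g+`` for
genes in any N, mutually exclusive per gene):

* solve for a minimum-cardinality selection satisfying accumulated cuts;
* if the selection does not block the target, the optimal flux ``v*``
  witnesses an unblocked route: add a cover cut requiring at least one
  GDict row of a reaction carrying flux in ``v*`` to be fully selected;
* if it blocks, greedily trim to inclusion-minimality (blocking is monotone
  in the intervention set), record the gMIS, and add a no-superset
  exclusion cut.

The loop terminates when the master becomes infeasible or ``max_solutions``
is reached; equal-cardinality solutions are reported in lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, milp

from .boolnet import InterventionSet
from .gdict_builder import GDict
from .model_io import MetabolicModel

__all__ = ["GMIS", "SolverConfig", "blocked_reactions", "blocks_target",
           "enumerate_gmis", "brute_force_gmis"]


@dataclass(frozen=True)
class GMIS:
    """A minimal intervention set together with the reactions it blocks."""

    interventions: InterventionSet
    blocked: frozenset[str]

    def sort_key(self):
        return self.interventions.sort_key()


@dataclass
class SolverConfig:
    max_size: int = 3
    max_solutions: int = 100
    flux_tol: float = 1e-6

    def __post_init__(self):
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if self.flux_tol <= 0:
            raise ValueError("flux_tol must be > 0")


def blocked_reactions(gdict: GDict, iv: InterventionSet) -> frozenset[str]:
    """Reactions with a GDict row (K, N) such that K ⊆ KO and N ⊆ KI."""
    out = set()
    for rid, rows in gdict.rows.items():
        for row in rows:
            if row.K <= iv.KO and row.N <= iv.KI:
                out.add(rid)
                break
    return frozenset(out)


def _max_target_flux(model: MetabolicModel, blocked: frozenset[str]) -> tuple[float, np.ndarray]:
    """LP optimum of the target flux and an optimal flux vector."""
    nr = len(model.reactions)
    c = np.zeros(nr)
    c[model.reaction_index(model.target)] = -1.0  # linprog minimizes
    bounds = [(model.lb[j], model.ub[j]) for j in range(nr)]
    for rid in blocked:
        bounds[model.reaction_index(rid)] = (0.0, 0.0)
    res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.S.shape[0]),
                  bounds=bounds, method="highs")
    if res.status == 3:  # unbounded target flux
        return np.inf, np.zeros(nr)
    if not res.success:
        raise RuntimeError(f"LP failed with status {res.status}: {res.message}")
    return -res.fun, res.x


def blocks_target(model: MetabolicModel, gdict: GDict, iv: InterventionSet,
                  cfg: SolverConfig | None = None) -> bool:
    """True iff the interventions make the target reaction infeasible.

    The LP optimum is normalized by the target's upper bound before the
    tolerance comparison, making the test scale-free.
    """
    cfg = cfg or SolverConfig()
    tub = model.ub[model.reaction_index(model.target)]
    if tub <= 0:
        raise ValueError("target reaction must have a positive upper bound")
    opt, _ = _max_target_flux(model, blocked_reactions(gdict, iv))
    return opt / tub <= cfg.flux_tol


def _flux_support(model: MetabolicModel, v: np.ndarray, tol: float) -> frozenset[str]:
    tub = model.ub[model.reaction_index(model.target)]
    return frozenset(model.reactions[j] for j in np.nonzero(np.abs(v) > tol * tub)[0])


def _trim_to_minimal(model: MetabolicModel, gdict: GDict, iv: InterventionSet,
                     cfg: SolverConfig) -> InterventionSet:
    """Greedy minimality: drop interventions whose removal still blocks.

    Blocking is monotone in the intervention set (more interventions fire at
    least the same rows), so single-removal trimming reaches an
    inclusion-minimal set.
    """
    changed = True
    while changed:
        changed = False
        for g in sorted(iv.KO):
            cand = InterventionSet(KO=iv.KO - {g}, KI=iv.KI)
            if blocks_target(model, gdict, cand, cfg):
                iv = cand
                changed = True
        for g in sorted(iv.KI):
            cand = InterventionSet(KO=iv.KO, KI=iv.KI - {g})
            if blocks_target(model, gdict, cand, cfg):
                iv = cand
                changed = True
    return iv


def enumerate_gmis(model: MetabolicModel, gdict: GDict,
                   cfg: SolverConfig | None = None) -> list[GMIS]:
    """Lazy cover-cut enumeration of all gMISs up to ``cfg.max_size``.

    Returns up to ``cfg.max_solutions`` inclusion-minimal blocking sets in
    canonical (size, lexicographic) order; an unblockable target yields an
    empty list.
    """
    cfg = cfg or SolverConfig()

    ko_genes = sorted({g for rows in gdict.rows.values() for r in rows for g in r.K})
    ki_genes = sorted({g for rows in gdict.rows.values() for r in rows for g in r.N})
    cand = [(g, "-") for g in ko_genes] + [(g, "+") for g in ki_genes]
    if not cand:
        return []
    vidx = {c: i for i, c in enumerate(cand)}
    all_rows = [row for rid in gdict.rows for row in gdict.rows[rid]]
    nvar = len(cand)
    nrow = len(all_rows)
    ntot = nvar + nrow  # selection vars then row-fired indicators

    # static constraints: row z_k <= each member selection; g-/g+ exclusivity;
    # cardinality cap
    A_rows, lows, highs = [], [], []

    def add(coeffs: dict[int, float], lo: float, hi: float):
        A_rows.append(coeffs)
        lows.append(lo)
        highs.append(hi)

    for k, row in enumerate(all_rows):
        members = [vidx[(g, "-")] for g in row.K] + [vidx[(g, "+")] for g in row.N]
        for m in members:
            add({nvar + k: 1.0, m: -1.0}, -np.inf, 0.0)  # z_k <= y_m
    for g in set(ko_genes) & set(ki_genes):
        add({vidx[(g, "-")]: 1.0, vidx[(g, "+")]: 1.0}, -np.inf, 1.0)
    add({i: 1.0 for i in range(nvar)}, -np.inf, float(cfg.max_size))

    cuts: list[tuple[dict[int, float], float, float]] = []
    solutions: list[GMIS] = []

    c = np.zeros(ntot)
    c[:nvar] = 1.0
    integrality = np.ones(ntot)

    while len(solutions) < cfg.max_solutions:
        rows_all = A_rows + [cut[0] for cut in cuts]
        lo_all = lows + [cut[1] for cut in cuts]
        hi_all = highs + [cut[2] for cut in cuts]
        data, ri, ci = [], [], []
        for i, coeffs in enumerate(rows_all):
            for j, val in coeffs.items():
                ri.append(i)
                ci.append(j)
                data.append(val)
        A = sp.csr_matrix((data, (ri, ci)), shape=(len(rows_all), ntot))
        res = milp(c=c, constraints=LinearConstraint(A, lo_all, hi_all),
                   integrality=integrality,
                   bounds=(np.zeros(ntot), np.ones(ntot)))
        if res.status != 0 or res.x is None:
            break  # infeasible: enumeration exhausted
        sel = res.x[:nvar] > 0.5
        iv = InterventionSet(KO=[g for (g, s), i in vidx.items() if s == "-" and sel[i]],
                             KI=[g for (g, s), i in vidx.items() if s == "+" and sel[i]])
        blocked = blocked_reactions(gdict, iv)
        opt, v = _max_target_flux(model, blocked)
        tub = model.ub[model.reaction_index(model.target)]
        if opt / tub <= cfg.flux_tol:
            iv = _trim_to_minimal(model, gdict, iv, cfg)
            solutions.append(GMIS(interventions=iv,
                                  blocked=blocked_reactions(gdict, iv)))
            # no-superset exclusion cut
            members = ([vidx[(g, "-")] for g in iv.KO] +
                       [vidx[(g, "+")] for g in iv.KI])
            cuts.append(({m: 1.0 for m in members}, -np.inf, float(len(members) - 1)))
        else:
            support = _flux_support(model, v, cfg.flux_tol)
            fire_rows = [k for k, row in enumerate(all_rows) if row.reaction in support]
            if not fire_rows:
                break  # an unblockable route exists: no selection can ever block
            cuts.append(({nvar + k: 1.0 for k in fire_rows}, 1.0, np.inf))

    return sorted(solutions, key=GMIS.sort_key)


def brute_force_gmis(model: MetabolicModel, gdict: GDict,
                     cfg: SolverConfig | None = None) -> list[GMIS]:
    """Oracle: scan every signed subset up to ``max_size`` with the LP check.

    Exhaustive and independent of the lazy-cut loop; intended for
    fixture-scale models only.
    """
    import itertools

    cfg = cfg or SolverConfig()
    ko_genes = sorted({g for rows in gdict.rows.values() for r in rows for g in r.K})
    ki_genes = sorted({g for rows in gdict.rows.values() for r in rows for g in r.N})
    cand = [(g, "-") for g in ko_genes] + [(g, "+") for g in ki_genes]
    hits: list[InterventionSet] = []
    for size in range(1, cfg.max_size + 1):
        for combo in itertools.combinations(cand, size):
            genes = [g for g, _ in combo]
            if len(set(genes)) < len(genes):
                continue  # g- and g+ of the same gene are mutually exclusive
            iv = InterventionSet(KO=[g for g, s in combo if s == "-"],
                                 KI=[g for g, s in combo if s == "+"])
            if blocks_target(model, gdict, iv, cfg):
                hits.append(iv)
    minimal = [iv for iv in hits
               if not any(o.issubset(iv) and o != iv for o in hits)]
    return sorted([GMIS(interventions=iv, blocked=blocked_reactions(gdict, iv))
                   for iv in minimal], key=GMIS.sort_key)
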