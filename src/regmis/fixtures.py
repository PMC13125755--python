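"""Self-contained toy fixtures with brute-forceable ground truth.

Everything the pipeline consumes — metabolic models, regulatory networks,
expression and dependency-score matrices — can be generated here at a scale
(at most a dozen Boolean nodes, a handful of metabolic genes) where the
exhaustive oracles in :mod:`regmis.boolnet` and
:func:`regmis.gmis_solver.brute_force_gmis` re-derive every stored ground
truth in seconds.  No download is ever required.

The two hand-built families are:

* the *toggle* fixture — a single reaction gated by one gene that sits
  downstream of a two-gene mutual-repression switch, the smallest network
  where cyclic regulation changes the intervention catalogue; and
* the *toy GEM* — two parallel routes from a fed metabolite to biomass,
  one gated by ``g1 and g2`` and one by ``g3``, in three regulatory
  variants (plain / activator ``r3 -> g3`` / repressor ``r4 -| g3``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boolnet import BooleanNetwork, InterventionSet
from .egpr import combine_regulators
from .model_io import (DependencyScores, ExpressionMatrix, Lit, MetabolicModel,
                       RegulatoryNetwork, parse_gpr, save_metabolic_model,
                       save_regulatory_network, save_sbml)

__all__ = ["FixtureBundle", "make_toggle_fixture", "make_toy_gem",
           "random_boolean_network", "make_screen_fixture", "emit_fixture"]

EXPR_HIGH = 5.0   # expression value for "on" genes (units: arbitrary, > default threshold)
EXPR_LOW = 0.0
SCORE_ESSENTIAL = -1.0   # depmap-style viability score for a truly essential gene
SCORE_NEUTRAL = 0.0


@dataclass
class FixtureBundle:
    """A toy model plus its regulatory network and frozen ground truth.

    ``ground_truth`` holds the expected GDict rows and gMIS list for the
    stated ``layers`` / ``kmax`` / ``max_size``; the values are re-derivable
    by the exhaustive oracles and asserted so in the test suite.
    """

    model: MetabolicModel
    regnet: RegulatoryNetwork
    ground_truth: dict
    expression: ExpressionMatrix | None = None
    scores: DependencyScores | None = None


def make_toggle_fixture() -> FixtureBundle:
    """Single reaction ``Rx`` (GPR ``g1``) fed by a mutual-repression switch.

    Edges: ``r1 -> g1`` (+), ``r1 -| r2``, ``r2 -| r1``.  At two regulatory
    layers the eGPR is the cyclic network ``Rx = g1, g1 = r1, r1 = not r2,
    r2 = not r1`` whose minimal inactivating sets are ``{g1-}``, ``{r1-}``
    and ``{r2+}``; at zero layers the catalogue collapses to ``{g1-}``.
    """
    model = MetabolicModel(
        reactions=["Rx"], metabolites=[], S=np.zeros((0, 1)),
        lb=np.zeros(1), ub=np.array([10.0]),
        gpr={"Rx": parse_gpr("g1")}, target="Rx", id="toggle")
    regnet = RegulatoryNetwork([("r1", "g1", 1), ("r1", "r2", -1), ("r2", "r1", -1)])
    ground_truth = {
        "layers": 2, "kmax": 1, "max_size": 1,
        "gdict": {"Rx": [{"K": ["g1"], "N": []},
                         {"K": ["r1"], "N": []},
                         {"K": [], "N": ["r2"]}]},
        "gdict_layers0": {"Rx": [{"K": ["g1"], "N": []}]},
        "gmis": [{"KO": ["g1"], "KI": []},
                 {"KO": ["r1"], "KI": []},
                 {"KO": [], "KI": ["r2"]}],
    }
    return FixtureBundle(model=model, regnet=regnet, ground_truth=ground_truth)


def make_toy_gem(variant: str = "plain") -> FixtureBundle:
    """Two parallel A -> B routes feeding a biomass drain (target ``R_bm``).

    ``R1`` needs ``g1 and g2``; ``R2`` needs ``g3``.  Variants:
    ``activator`` adds ``r3 -> g3``; ``repressor`` additionally adds
    ``r4 -| g3`` (so at one layer ``g3 = r3 and not r4``).  Ground-truth
    gMIS lists (size <= 2) are frozen from the exhaustive signed-subset + LP
    oracle.
    """
    if variant not in ("plain", "activator", "repressor"):
        raise ValueError(f"unknown variant {variant!r}")
    reactions = ["R_upt", "R1", "R2", "R_bm"]
    metabolites = ["A", "B"]
    S = np.array([
        [1.0, -1.0, -1.0, 0.0],   # A
        [0.0, 1.0, 1.0, -1.0],    # B
    ])
    model = MetabolicModel(
        reactions=reactions, metabolites=metabolites, S=S,
        lb=np.zeros(4), ub=np.full(4, 10.0),
        gpr={"R1": parse_gpr("g1 and g2"), "R2": parse_gpr("g3")},
        target="R_bm", id=f"toy_gem_{variant}")

    edges = []
    if variant in ("activator", "repressor"):
        edges.append(("r3", "g3", 1))
    if variant == "repressor":
        edges.append(("r4", "g3", -1))
    regnet = RegulatoryNetwork(edges)

    r1_rows = [{"K": ["g1"], "N": []}, {"K": ["g2"], "N": []}]
    if variant == "plain":
        r2_rows = [{"K": ["g3"], "N": []}]
        gmis = [{"KO": ["g1", "g3"], "KI": []}, {"KO": ["g2", "g3"], "KI": []}]
    elif variant == "activator":
        r2_rows = [{"K": ["g3"], "N": []}, {"K": ["r3"], "N": []}]
        gmis = [{"KO": ["g1", "g3"], "KI": []}, {"KO": ["g1", "r3"], "KI": []},
                {"KO": ["g2", "g3"], "KI": []}, {"KO": ["g2", "r3"], "KI": []}]
    else:
        r2_rows = [{"K": ["g3"], "N": []}, {"K": ["r3"], "N": []},
                   {"K": [], "N": ["r4"]}]
        gmis = [{"KO": ["g1"], "KI": ["r4"]}, {"KO": ["g1", "g3"], "KI": []},
                {"KO": ["g1", "r3"], "KI": []}, {"KO": ["g2"], "KI": ["r4"]},
                {"KO": ["g2", "g3"], "KI": []}, {"KO": ["g2", "r3"], "KI": []}]
    ground_truth = {
        "layers": 0 if variant == "plain" else 1, "kmax": 2, "max_size": 2,
        "gdict": {"R1": r1_rows, "R2": r2_rows},
        "gmis": gmis,
    }
    return FixtureBundle(model=model, regnet=regnet, ground_truth=ground_truth)


def random_boolean_network(n: int, max_indegree: int, seed: int) -> BooleanNetwork:
    """Seeded random network: each node gets 0..max_indegree signed regulators.

    Regulator sets and signs are drawn from one seeded stream; regulators
    are combined with the standard OR-of-activators AND NOT-OR-of-repressors
    rule, nodes without regulators stay free inputs.  Same seed, same
    network.
    """
    if n < 1 or max_indegree < 1:
        raise ValueError("n and max_indegree must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(n)]
    f = {}
    for x in nodes:
        d = int(rng.integers(0, max_indegree + 1))
        if d == 0:
            f[x] = Lit(x)
            continue
        regs = [str(g) for g in rng.choice(nodes, size=min(d, n), replace=False)]
        signs = rng.integers(0, 2, size=len(regs))
        acts = [g for g, s in zip(regs, signs) if s == 1]
        reps = [g for g, s in zip(regs, signs) if s == 0]
        f[x] = combine_regulators(acts, reps)
    return BooleanNetwork(f)


def _truth_calls(gmis_truth: list[dict], expr_col: pd.Series, threshold: float) -> set[str]:
    """Planted essentiality rule, written out independently of screening code."""
    calls = set()
    for gm in gmis_truth:
        ko, ki = gm["KO"], gm["KI"]
        if not all(expr_col[g] > threshold for g in ki):
            continue
        high_kos = [g for g in ko if expr_col[g] > threshold]
        if len(high_kos) == 1:
            calls.add(high_kos[0])
    return calls


def make_screen_fixture(bundle: FixtureBundle, n_samples: int = 8,
                        noise: float = 0.0, seed: int = 0,
                        expr_threshold: float = 1.0) -> FixtureBundle:
    """Attach a synthetic expression matrix and dependency screen.

    Per sample a random subset of the gMIS context genes is silenced (the
    rest set high); dependency scores are -1.0 (DepMap convention) for genes
    that are truly essential under the planted gMIS rule and 0.0 otherwise,
    with a fraction ``noise`` of labels flipped.  Two deterministic control
    samples (one producing a call, one with every context gene on) ensure
    the noise-free pooled confusion contains both a true positive and a
    true negative, so it is never degenerate.
    """
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (two control samples)")
    gmis_truth = bundle.ground_truth["gmis"]
    context = sorted({g for gm in gmis_truth for g in gm["KO"] + gm["KI"]})
    ko_universe = sorted({g for gm in gmis_truth for g in gm["KO"]})
    rng = np.random.default_rng(seed)

    columns = {}
    first = gmis_truth[0]
    pos = {g: EXPR_LOW for g in context}
    pos[sorted(first["KO"])[0]] = EXPR_HIGH
    for g in first["KI"]:
        pos[g] = EXPR_HIGH
    columns["s_ctrl_pos"] = pos
    columns["s_ctrl_neg"] = {g: EXPR_HIGH for g in context}
    for i in range(n_samples - 2):
        on = rng.random(len(context)) < 0.5
        columns[f"s{i:02d}"] = {g: (EXPR_HIGH if o else EXPR_LOW)
                                for g, o in zip(context, on)}
    expr_df = pd.DataFrame({s: [cols[g] for g in context]
                            for s, cols in columns.items()}, index=context)

    score_df = pd.DataFrame(SCORE_NEUTRAL, index=ko_universe,
                            columns=list(columns), dtype=float)
    for s in columns:
        essential = _truth_calls(gmis_truth, expr_df[s], expr_threshold)
        for g in essential:
            score_df.at[g, s] = SCORE_ESSENTIAL
    flip = rng.random(score_df.shape) < noise
    flipped = score_df.where(~flip, SCORE_ESSENTIAL + SCORE_NEUTRAL - score_df)

    return FixtureBundle(model=bundle.model, regnet=bundle.regnet,
                         ground_truth=dict(bundle.ground_truth),
                         expression=ExpressionMatrix(expr_df),
                         scores=DependencyScores(flipped, platform="depmap"))


def emit_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Materialize the bundle as files in the standard formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["model"] = outdir / "model.json"
    save_metabolic_model(bundle.model, paths["model"])
    paths["sbml"] = outdir / "model.sbml"
    save_sbml(bundle.model, paths["sbml"])
    paths["regnet"] = outdir / "regnet.tsv"
    save_regulatory_network(bundle.regnet, paths["regnet"])
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(
        json.dumps(bundle.ground_truth, sort_keys=True, indent=1) + "\n")
    if bundle.expression is not None:
        paths["expression"] = outdir / "expression.csv"
        bundle.expression.values.to_csv(paths["expression"])
    if bundle.scores is not None:
        paths["scores"] = outdir / "scores.csv"
        bundle.scores.values.to_csv(paths["scores"])
    return paths
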