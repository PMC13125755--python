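"""Input/output for metabolic models, GPR rules, regulatory networks and matrices.

A metabolic model couples a stoichiometric matrix ``S`` (metabolites x
reactions) with flux bounds and per-reaction gene-protein-reaction (GPR)
rules: Boolean expressions over gene identifiers stating when the reaction's
catalyst is available.  Models are read either from SBML (through cobrapy,
using the fbc package for GPRs) or from a small JSON dialect documented in
:func:`save_metabolic_model`.  Regulatory networks are signed edge lists in a
three-column TSV; expression and dependency-score matrices are CSV with gene
rows and sample columns.

Gene identifiers are opaque strings throughout; no identifier mapping is
performed.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("regmis")

__all__ = [
    "BooleanExpr", "Const", "Lit", "Not", "And", "Or",
    "GPRParseError", "ModelFormatError",
    "parse_gpr", "MetabolicModel", "load_metabolic_model", "save_metabolic_model",
    "RegulatoryNetwork", "load_regulatory_network", "save_regulatory_network",
    "ExpressionMatrix", "DependencyScores", "load_matrix",
    "save_gdict", "load_gdict",
]


# ---------------------------------------------------------------------------
# Boolean expressions
# ---------------------------------------------------------------------------

class BooleanExpr:
    """Base class for GPR / update-function expression trees.

    Nodes are immutable and compared structurally.  Conjunction and
    disjunction are flattened on construction (``AND(AND(a,b),c)`` becomes
    ``AND(a,b,c)``) so that parse -> render -> parse is the identity.
    """

    __slots__ = ()

    def variables(self) -> tuple[str, ...]:
        """Sorted tuple of distinct literal names appearing in the tree."""
        out: set[str] = set()
        self._collect(out)
        return tuple(sorted(out))

    def _collect(self, out: set) -> None:
        raise NotImplementedError

    def evaluate(self, env: Mapping[str, int]) -> int:
        """Evaluate under a total assignment of the expression's variables."""
        raise NotImplementedError

    def substitute(self, env: Mapping[str, "BooleanExpr"]) -> "BooleanExpr":
        """Replace literals by expressions (missing literals left intact)."""
        raise NotImplementedError

    def render(self) -> str:
        """Canonical text form: lowercase keywords, minimal parentheses."""
        return self._render(0)

    def _render(self, prec: int) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.render()!r})"


@dataclass(frozen=True, repr=False)
class Const(BooleanExpr):
    value: int  # 0 or 1

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ValueError("Const value must be 0 or 1")

    def _collect(self, out):
        pass

    def evaluate(self, env):
        return self.value

    def substitute(self, env):
        return self

    def _render(self, prec):
        return str(self.value)


@dataclass(frozen=True, repr=False)
class Lit(BooleanExpr):
    name: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("empty gene token")

    def _collect(self, out):
        out.add(self.name)

    def evaluate(self, env):
        return int(bool(env[self.name]))

    def substitute(self, env):
        return env.get(self.name, self)

    def _render(self, prec):
        return self.name


@dataclass(frozen=True, repr=False)
class Not(BooleanExpr):
    arg: BooleanExpr

    def _collect(self, out):
        self.arg._collect(out)

    def evaluate(self, env):
        return 1 - self.arg.evaluate(env)

    def substitute(self, env):
        return Not(self.arg.substitute(env))

    def _render(self, prec):
        inner = self.arg._render(3)
        return f"not {inner}"


def _flatten(cls, args: Sequence[BooleanExpr]) -> tuple[BooleanExpr, ...]:
    flat: list[BooleanExpr] = []
    for a in args:
        if isinstance(a, cls):
            flat.extend(a.args)
        else:
            flat.append(a)
    return tuple(flat)


@dataclass(frozen=True, repr=False)
class And(BooleanExpr):
    args: tuple[BooleanExpr, ...]

    def __init__(self, *args: BooleanExpr):
        if len(args) == 1 and isinstance(args[0], (tuple, list)):
            args = tuple(args[0])
        if len(args) < 2:
            raise ValueError("And requires at least two operands")
        object.__setattr__(self, "args", _flatten(And, args))

    def _collect(self, out):
        for a in self.args:
            a._collect(out)

    def evaluate(self, env):
        for a in self.args:
            if not a.evaluate(env):
                return 0
        return 1

    def substitute(self, env):
        return And(*[a.substitute(env) for a in self.args])

    def _render(self, prec):
        s = " and ".join(a._render(2) for a in self.args)
        return f"({s})" if prec > 1 else s


@dataclass(frozen=True, repr=False)
class Or(BooleanExpr):
    args: tuple[BooleanExpr, ...]

    def __init__(self, *args: BooleanExpr):
        if len(args) == 1 and isinstance(args[0], (tuple, list)):
            args = tuple(args[0])
        if len(args) < 2:
            raise ValueError("Or requires at least two operands")
        object.__setattr__(self, "args", _flatten(Or, args))

    def _collect(self, out):
        for a in self.args:
            a._collect(out)

    def evaluate(self, env):
        for a in self.args:
            if a.evaluate(env):
                return 1
        return 0

    def substitute(self, env):
        return Or(*[a.substitute(env) for a in self.args])

    def _render(self, prec):
        s = " or ".join(a._render(1) for a in self.args)
        return f"({s})" if prec > 0 else s


class GPRParseError(ValueError):
    """Raised when a GPR / Boolean rule string cannot be parsed."""


class ModelFormatError(ValueError):
    """Raised when an input file violates its declared format."""


_TOKEN_RE = re.compile(r"\(|\)|&&?|\|\|?|!|[A-Za-z0-9_.:\-]+")


def _tokenize(text: str) -> list[str]:
    tokens = _TOKEN_RE.findall(text)
    leftover = _TOKEN_RE.sub(" ", text)
    if leftover.strip():
        raise GPRParseError(
            f"unexpected characters {leftover.strip().split()[0]!r} in rule {text!r}")
    return tokens


def parse_gpr(text: str) -> BooleanExpr:
    """Parse a GPR rule into a :class:`BooleanExpr`.

    The grammar accepts ``and``/``or``/``not`` (case-insensitive) as well as
    the ``&``/``|``/``!`` spellings used by some model dialects, with
    precedence NOT > AND > OR and parentheses.  ``1``/``0`` (and
    ``true``/``false``) denote constants.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRParseError("empty GPR rule")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def kw(tok):
        return tok.lower() if tok and tok.lower() in ("and", "or", "not", "true", "false") else tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and kw(peek()) in ("or", "|", "||"):
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def parse_and():
        terms = [parse_not()]
        while peek() is not None and kw(peek()) in ("and", "&", "&&"):
            take()
            terms.append(parse_not())
        return terms[0] if len(terms) == 1 else And(*terms)

    def parse_not():
        if peek() is not None and kw(peek()) in ("not", "!"):
            take()
            return Not(parse_not())
        return parse_atom()

    def parse_atom():
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule {text!r} (empty operand)")
        if tok == "(":
            take()
            e = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in rule {text!r}")
            take()
            return e
        if tok == ")":
            raise GPRParseError(f"unbalanced parentheses in rule {text!r}")
        tok = take()
        low = tok.lower()
        if low in ("and", "or", "not", "&", "|", "!"):
            raise GPRParseError(f"operator {tok!r} where an operand was expected in {text!r}")
        if low in ("0", "false"):
            return Const(0)
        if low in ("1", "true"):
            return Const(1)
        return Lit(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens {tokens[pos:]} in rule {text!r}")
    return expr


# ---------------------------------------------------------------------------
# Metabolic model
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """Constraint-based metabolic model with GPR rules and a target reaction.

    ``S`` is the stoichiometric matrix (|metabolites| x |reactions|); ``lb``
    and ``ub`` are per-reaction flux bounds; ``gpr`` maps reaction id to a
    Boolean expression over gene ids (reactions without an entry are
    genetically unconstrained, i.e. ``Const(1)``); ``target`` names the
    reaction whose blocking defines the intervention objective (typically a
    biomass or demand reaction).
    """

    reactions: list[str]
    metabolites: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gpr: dict[str, BooleanExpr]
    target: str
    id: str = "model"

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    def validate(self) -> None:
        nm, nr = len(self.metabolites), len(self.reactions)
        if self.S.shape != (nm, nr):
            raise ModelFormatError(
                f"S has shape {self.S.shape}, expected ({nm}, {nr})")
        if self.lb.shape != (nr,) or self.ub.shape != (nr,):
            raise ModelFormatError("lb/ub must have one entry per reaction")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            raise ModelFormatError(
                f"lb > ub for reaction(s) {[self.reactions[i] for i in bad]}")
        if self.target not in self.reactions:
            raise ModelFormatError(f"target reaction {self.target!r} not in model")
        for rid, expr in self.gpr.items():
            if rid not in self.reactions:
                raise ModelFormatError(f"GPR for unknown reaction {rid!r}")
            for g in expr.variables():
                if not g:
                    raise ModelFormatError(f"empty gene token in GPR of {rid!r}")

    def gpr_of(self, rid: str) -> BooleanExpr:
        return self.gpr.get(rid, Const(1))

    def genes(self) -> list[str]:
        out: set[str] = set()
        for expr in self.gpr.values():
            out.update(expr.variables())
        return sorted(out)

    def reaction_index(self, rid: str) -> int:
        return self.reactions.index(rid)


def save_metabolic_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the JSON model dialect.

    Layout::

        {"id": ..., "target": ...,
         "metabolites": [...],
         "reactions": [{"id":..., "lb":..., "ub":..., "gpr": "<rule or null>",
                        "metabolites": {met: coeff, ...}}, ...]}

    Keys are sorted so serialization is canonical and diffable.
    """
    rxns = []
    for j, rid in enumerate(model.reactions):
        col = model.S[:, j]
        mets = {model.metabolites[i]: col[i] for i in np.nonzero(col)[0]}
        entry = {
            "id": rid,
            "lb": float(model.lb[j]),
            "ub": float(model.ub[j]),
            "gpr": model.gpr[rid].render() if rid in model.gpr else None,
            "metabolites": mets,
        }
        rxns.append(entry)
    doc = {
        "id": model.id,
        "target": model.target,
        "metabolites": list(model.metabolites),
        "reactions": rxns,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def _model_from_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    for key in ("metabolites", "reactions", "target"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level key {key!r}")
    metabolites = list(doc["metabolites"])
    reactions, lb, ub, gpr = [], [], [], {}
    met_index = {m: i for i, m in enumerate(metabolites)}
    S = np.zeros((len(metabolites), len(doc["reactions"])))
    for j, r in enumerate(doc["reactions"]):
        rid = r["id"]
        reactions.append(rid)
        lb.append(r["lb"])
        ub.append(r["ub"])
        if r.get("gpr"):
            try:
                gpr[rid] = parse_gpr(r["gpr"])
            except GPRParseError as e:
                raise ModelFormatError(f"{path}: reaction {rid!r}: {e}") from e
        for met, coeff in r.get("metabolites", {}).items():
            if met not in met_index:
                raise ModelFormatError(f"{path}: reaction {rid!r} uses unknown metabolite {met!r}")
            S[met_index[met], j] = coeff
    return MetabolicModel(reactions, metabolites, S, np.array(lb), np.array(ub),
                          gpr, doc["target"], id=doc.get("id", path.stem))


def _model_from_sbml(path: Path, target: str | None) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as e:  # cobra raises a mix of libsbml/IO errors
        raise ModelFormatError(f"{path}: SBML parse failure: {e}") from e
    reactions = [r.id for r in cm.reactions]
    metabolites = [m.id for m in cm.metabolites]
    S = np.zeros((len(metabolites), len(reactions)))
    midx = {m: i for i, m in enumerate(metabolites)}
    lb, ub, gpr = [], [], {}
    for j, r in enumerate(cm.reactions):
        lb.append(r.lower_bound)
        ub.append(r.upper_bound)
        for met, coeff in r.metabolites.items():
            S[midx[met.id], j] = coeff
        rule = r.gene_reaction_rule
        if rule and rule.strip():
            gpr[r.id] = parse_gpr(rule)
    if target is None:
        objs = [r.id for r in cm.reactions if r.objective_coefficient]
        if len(objs) != 1:
            raise ModelFormatError(
                f"{path}: cannot infer target reaction (objective has {len(objs)} reactions); "
                "pass target= explicitly")
        target = objs[0]
    return MetabolicModel(reactions, metabolites, S, np.array(lb), np.array(ub),
                          gpr, target, id=cm.id or path.stem)


def load_metabolic_model(path: str | Path, format: str = "json",
                         target: str | None = None) -> MetabolicModel:
    """Load a metabolic model from ``json`` (native dialect) or ``sbml``.

    SBML files carry no target annotation; the target defaults to the single
    objective reaction, or must be passed explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        model = _model_from_json(path)
        if target is not None:
            model.target = target
            model.validate()
        return model
    if format == "sbml":
        return _model_from_sbml(path, target)
    raise ValueError(f"unknown model format {format!r}")


def save_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML (fbc GPRs) through cobrapy."""
    import cobra
    import cobra.io

    cm = cobra.Model(model.id)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for j, rid in enumerate(model.reactions):
        r = cobra.Reaction(rid, lower_bound=float(model.lb[j]), upper_bound=float(model.ub[j]))
        rxns.append(r)
    cm.add_reactions(rxns)
    for j, rid in enumerate(model.reactions):
        r = cm.reactions.get_by_id(rid)
        col = model.S[:, j]
        r.add_metabolites({mets[model.metabolites[i]]: float(col[i])
                           for i in np.nonzero(col)[0]})
        if rid in model.gpr:
            r.gene_reaction_rule = model.gpr[rid].render()
    cm.objective = cm.reactions.get_by_id(model.target)
    cobra.io.write_sbml_model(cm, str(path))


# ---------------------------------------------------------------------------
# Regulatory network
# ---------------------------------------------------------------------------

_SIGN_TOKENS = {
    "+": 1, "+1": 1, "1": 1, "activation": 1,
    "-": -1, "-1": -1, "−1": -1, "−": -1, "repression": -1,
}


@dataclass
class RegulatoryNetwork:
    """Signed directed gene-regulatory edge list.

    ``edges`` holds ``(source, target, sign)`` triples with sign in
    ``{+1, -1}``; duplicates are collapsed, but a pair regulated with both
    signs keeps both edges.
    """

    edges: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        dedup = []
        for s, t, sg in self.edges:
            if sg not in (1, -1):
                raise ValueError(f"edge ({s}, {t}) has invalid sign {sg}")
            if (s, t, sg) not in seen:
                seen.add((s, t, sg))
                dedup.append((s, t, sg))
        self.edges = dedup

    def regulators_of(self, gene: str) -> tuple[list[str], list[str]]:
        """Activators and repressors of ``gene``, each sorted."""
        acts = sorted({s for s, t, sg in self.edges if t == gene and sg == 1})
        reps = sorted({s for s, t, sg in self.edges if t == gene and sg == -1})
        return acts, reps

    def genes(self) -> list[str]:
        out = set()
        for s, t, _ in self.edges:
            out.add(s)
            out.add(t)
        return sorted(out)


def load_regulatory_network(path: str | Path) -> RegulatoryNetwork:
    """Load a 3-column (source, target, sign) TSV without header.

    Sign tokens: ``+ - +1 -1 1 activation repression`` (and the unicode
    minus).  Exact duplicate rows collapse to one edge; a (source, target)
    pair appearing with both signs keeps both edges and logs a warning.
    """
    path = Path(path)
    edges: list[tuple[str, str, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ModelFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            src, tgt, tok = (p.strip() for p in parts)
            if tok not in _SIGN_TOKENS:
                raise ModelFormatError(f"{path}:{lineno}: unknown sign token {tok!r}")
            if not src or not tgt:
                raise ModelFormatError(f"{path}:{lineno}: empty gene id")
            edges.append((src, tgt, _SIGN_TOKENS[tok]))
    net = RegulatoryNetwork(edges)
    pair_signs: dict[tuple[str, str], set[int]] = {}
    for s, t, sg in net.edges:
        pair_signs.setdefault((s, t), set()).add(sg)
    for (s, t), signs in pair_signs.items():
        if len(signs) > 1:
            logger.warning("conflicting signs for regulatory pair %s -> %s; both edges kept", s, t)
    return net


def save_regulatory_network(net: RegulatoryNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s, t, sg in net.edges:
            fh.write(f"{s}\t{t}\t{'+' if sg == 1 else '-'}\n")


# ---------------------------------------------------------------------------
# Expression / dependency-score matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (units as provided, e.g. TPM)."""

    values: pd.DataFrame

    def __post_init__(self):
        _check_matrix(self.values, allow_missing=False)


@dataclass
class DependencyScores:
    """Genes x samples dependency scores from a knockout screen.

    ``platform`` selects the essentiality convention: ``depmap`` scores are
    viability effects (essential when strongly negative) while
    ``project_score`` provides loss-of-fitness scores (essential when
    positive).  Missing values (NaN) are permitted and excluded from
    evaluation downstream.
    """

    values: pd.DataFrame
    platform: str

    def __post_init__(self):
        if self.platform not in ("depmap", "project_score"):
            raise ValueError(f"unknown platform {self.platform!r}")
        _check_matrix(self.values, allow_missing=True)


def _check_matrix(df: pd.DataFrame, allow_missing: bool) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ModelFormatError(f"duplicated gene id(s): {dups}")
    if df.shape[1] == 0:
        raise ModelFormatError("matrix has no sample columns")
    if any(not g for g in df.index):
        raise ModelFormatError("empty gene id in matrix index")
    vals = df.to_numpy(dtype=float)
    if not allow_missing and not np.isfinite(vals).all():
        i, j = np.argwhere(~np.isfinite(vals))[0]
        raise ModelFormatError(
            f"non-finite value at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    if allow_missing and np.isinf(vals).any():
        i, j = np.argwhere(np.isinf(vals))[0]
        raise ModelFormatError(
            f"infinite value at gene {df.index[i]!r}, sample {df.columns[j]!r}")


def load_matrix(path: str | Path, kind: str, platform: str | None = None):
    """Load a genes x samples CSV as expression values or dependency scores.

    The first column holds gene ids, the header row sample ids.  Non-numeric
    cells raise with their coordinates; duplicated gene rows are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            gene = df.index[bad.argmax()]
            raise ModelFormatError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        df[col] = converted
    if kind == "expression":
        return ExpressionMatrix(df)
    if kind == "scores":
        if platform is None:
            raise ValueError("platform required for kind='scores'")
        return DependencyScores(df, platform)
    raise ValueError(f"unknown matrix kind {kind!r}")


# ---------------------------------------------------------------------------
# GDict serialization
# ---------------------------------------------------------------------------

_PROVENANCE_KEY = "__provenance__"


def save_gdict(gdict, path: str | Path) -> None:
    """Serialize a GDict as ``{reaction_id: [{"K": [...], "N": [...]}, ...]}``.

    Provenance (layers, kmax, model id) goes under a reserved
    ``__provenance__`` key; reaction ids must not collide with it.  Output is
    canonical JSON (sorted keys) so artifacts are diffable.
    """
    doc: dict = {}
    for rid, rows in gdict.rows.items():
        if rid == _PROVENANCE_KEY:
            raise ValueError(f"reaction id collides with reserved key {_PROVENANCE_KEY}")
        doc[rid] = [{"K": sorted(row.K), "N": sorted(row.N)} for row in rows]
    if gdict.provenance:
        doc[_PROVENANCE_KEY] = dict(gdict.provenance)
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def load_gdict(path: str | Path):
    """Deserialize and validate a GDict written by :func:`save_gdict`."""
    from .gdict_builder import GDict, InterventionRow

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    if not isinstance(doc, dict):
        raise ModelFormatError(f"{path}: top-level JSON object expected")
    provenance = doc.pop(_PROVENANCE_KEY, {})
    rows: dict[str, list[InterventionRow]] = {}
    for rid, entries in doc.items():
        out = []
        for k, entry in enumerate(entries):
            K = frozenset(entry.get("K", []))
            N = frozenset(entry.get("N", []))
            if K & N:
                raise ModelFormatError(
                    f"{path}: reaction {rid!r} row {k}: gene(s) {sorted(K & N)} in both K and N")
            if not (K | N):
                raise ModelFormatError(f"{path}: reaction {rid!r} row {k}: empty intervention")
            out.append(InterventionRow(K=K, N=N, reaction=rid))
        rows[rid] = out
    return GDict(rows=rows, provenance=provenance)
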