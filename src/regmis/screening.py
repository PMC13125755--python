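"""Expression-conditioned essentiality prediction and screen-based scoring.

A gMIS ``{g1-, g2-}`` predicts a context-specific single-gene vulnerability:
in a sample where g1 is not expressed, the cell effectively lives with the
g1 knockout already in place, so knocking out g2 alone should be lethal.
Generally a knockout member is called essential in a sample when it is the
*unique* highly expressed gene among the gMIS knockouts and every knock-in
member is highly expressed (the knock-in context is already on, so only the
remaining knockout is needed).

Predictions are validated against CRISPR dependency screens: DepMap calls a
gene essential at score <= -0.6 (boundary essential), Project Score at
score > 0 (boundary non-essential).  Agreement is scored with Matthews
correlation coefficient (MCC), which balances all four confusion classes.

An attractor-based *adaptation check* guards against regulatory rescue: for
each single knockout of a gMIS, the perturbed network must still admit an
attractor in which the remaining members keep their intervention-consistent
states; if the network instead re-adapts (another knockout member switches
on, or a knock-in member off), the gMIS is flagged and its predictions
discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .boolnet import BooleanNetwork, InterventionSet, apply_perturbation, minimal_trap_spaces
from .gmis_solver import GMIS
from .model_io import DependencyScores, ExpressionMatrix

__all__ = ["ScreeningConfig", "ConfusionCounts", "EvaluationResult",
           "predict_essential", "adaptation_check", "label_dependencies",
           "compute_mcc", "evaluate_predictions"]


@dataclass
class ScreeningConfig:
    """Thresholds for binarization and screen labeling.

    ``expr_high_threshold`` is in the expression units of the input matrix
    (default 1.0, e.g. TPM); a gene is "highly expressed" when strictly
    above it.  The dependency cutoffs follow the screens' conventions:
    DepMap essential iff score <= -0.6, Project Score essential iff
    score > 0.
    """

    expr_high_threshold: float = 1.0
    depmap_essential_cutoff: float = -0.6
    project_score_essential_cutoff: float = 0.0

    def __post_init__(self):
        for v in (self.expr_high_threshold, self.depmap_essential_cutoff,
                  self.project_score_essential_cutoff):
            if not math.isfinite(v):
                raise ValueError("screening cutoffs must be finite")


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass
class EvaluationResult:
    per_sample: dict[str, ConfusionCounts]
    per_sample_mcc: dict[str, float]
    pooled: ConfusionCounts
    pooled_mcc: float


def compute_mcc(c: ConfusionCounts) -> float:
    """(TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 on zero factor."""
    denom = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def predict_essential(gmis_list: list[GMIS], expr: ExpressionMatrix,
                      cfg: ScreeningConfig | None = None
                      ) -> dict[str, dict[str, list[int]]]:
    """Per-sample essential-gene calls from gMISs and expression context.

    Gene ``g`` is predicted essential in sample ``s`` iff some gMIS has
    ``g`` in its knockout set, ``g`` is highly expressed in ``s``, every
    *other* knockout member is not highly expressed, and every knock-in
    member is highly expressed.  Returns
    ``{sample: {gene: [indices of supporting gMISs]}}`` so each call keeps
    its provenance.
    """
    cfg = cfg or ScreeningConfig()
    df = expr.values
    needed = set()
    for gm in gmis_list:
        needed |= gm.interventions.KO | gm.interventions.KI
    missing = sorted(needed - set(df.index))
    if missing:
        raise KeyError(f"gene(s) absent from the expression matrix: {missing}")
    high = df > cfg.expr_high_threshold
    out: dict[str, dict[str, list[int]]] = {s: {} for s in df.columns}
    for s in df.columns:
        hs = high[s]
        for idx, gm in enumerate(gmis_list):
            ko, ki = gm.interventions.KO, gm.interventions.KI
            if not all(hs[g] for g in ki):
                continue
            expressed = [g for g in ko if hs[g]]
            if len(expressed) == 1:
                g = expressed[0]
                out[s].setdefault(g, []).append(idx)
    return out


def adaptation_check(bn: BooleanNetwork, gmis: GMIS,
                     perturb_each_ko: bool = True) -> bool:
    """Attractor-based rescue check for one gMIS; True = pass.

    For each knockout member applied alone, the perturbed network must admit
    at least one minimal trap space where no *other* knockout member is
    fixed to 1 and no knock-in member is fixed to 0.  Failing any single
    knockout flags the whole gMIS.  With ``perturb_each_ko=False`` the
    broader reading is used: every member is perturbed singly with its own
    sign (knock-ins pinned to 1 as well) and the remaining members are
    observed the same way.
    """
    ko, ki = gmis.interventions.KO, gmis.interventions.KI
    missing = (ko | ki) - set(bn.nodes)
    if missing:
        raise ValueError(f"gMIS gene(s) {sorted(missing)} not in network")

    def admits_consistent_space(gene: str, sign: str) -> bool:
        p = InterventionSet(KO=[gene]) if sign == "-" else InterventionSet(KI=[gene])
        pbn = apply_perturbation(bn, p)
        for ts in minimal_trap_spaces(pbn):
            if any(ts.get(g) == 1 for g in ko - {gene}):
                continue
            if any(ts.get(g) == 0 for g in ki - {gene}):
                continue
            return True
        return False

    members = [(g, "-") for g in sorted(ko)]
    if not perturb_each_ko:
        members += [(g, "+") for g in sorted(ki)]
    return all(admits_consistent_space(g, s) for g, s in members)


def label_dependencies(scores: DependencyScores, cfg: ScreeningConfig | None = None
                       ) -> pd.DataFrame:
    """Binary essentiality labels from a dependency screen.

    DepMap: essential iff score <= -0.6; Project Score: essential iff
    score > 0.  Missing scores stay NaN and are excluded from evaluation.
    """
    cfg = cfg or ScreeningConfig()
    df = scores.values.astype(float)
    if scores.platform == "depmap":
        labels = (df <= cfg.depmap_essential_cutoff).astype(float)
    elif scores.platform == "project_score":
        labels = (df > cfg.project_score_essential_cutoff).astype(float)
    else:  # pragma: no cover - guarded in DependencyScores
        raise ValueError(f"unknown platform {scores.platform!r}")
    labels[df.isna()] = float("nan")
    return labels


def evaluate_predictions(pred: dict[str, dict[str, list[int]]] | dict[str, set[str]],
                         labels: pd.DataFrame,
                         universe: set[str]) -> EvaluationResult:
    """Confusion counts and MCC, per sample and pooled.

    Counts run over ``universe`` genes that carry a (non-missing) label in
    each sample: TP = predicted & essential, FP = predicted & not,
    FN = unpredicted & essential, TN = the rest.  Pooled counts are the
    per-sample sums; MCC uses the zero-denominator -> 0 convention.
    """
    if not universe:
        raise ValueError("evaluation universe is empty")
    unlabeled = sorted(set(universe) - set(labels.index))
    if unlabeled:
        raise KeyError(f"universe gene(s) without labels: {unlabeled}")
    per_sample: dict[str, ConfusionCounts] = {}
    per_mcc: dict[str, float] = {}
    pooled = ConfusionCounts()
    for s in labels.columns:
        called = set(pred.get(s, {}))
        c = ConfusionCounts()
        for g in sorted(universe):
            lab = labels.at[g, s]
            if pd.isna(lab):
                continue
            essential = bool(lab)
            predicted = g in called
            if predicted and essential:
                c.TP += 1
            elif predicted:
                c.FP += 1
            elif essential:
                c.FN += 1
            else:
                c.TN += 1
        per_sample[s] = c
        per_mcc[s] = compute_mcc(c)
        pooled = pooled + c
    return EvaluationResult(per_sample=per_sample, per_sample_mcc=per_mcc,
                            pooled=pooled, pooled_mcc=compute_mcc(pooled))
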