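"""Classification of predicted models and ensemble-level statistics.

A model is called *accurate* when its fold-switching region lies within
3 Å of either experimentally determined conformation and its average
confidence (plDDT over the region) is at least 55.  A model with plDDT of
70 or more is *high-confidence*; a high-confidence model matching neither
reference, or matching a conformation never observed experimentally, is a
false positive.  A protein is called metamorphic when confident accurate
models of both conformations exist, and a single folder when only one is
recovered.

Ensemble comparisons use a 2x2 confusion table with one decision per
(protein, conformation) pair — predicted = a confident accurate model of
that conformation exists; observed = the conformation is experimentally
confirmed — summarized by the Matthews Correlation Coefficient and the
fraction of correct decisions (%success).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import ParameterError, ValidationError
from .structure import DualRMSD

logger = logging.getLogger(__name__)

GROUND = "ground"
ALTERNATIVE = "alternative"
NEITHER = "neither"
CONFORMATIONS = (GROUND, ALTERNATIVE)


@dataclass
class ClassificationThresholds:
    """Thresholds for model classification.

    accurate_rmsd: max RMSD (Å) to a reference for an accurate call.
    accurate_plddt: min mean plDDT for an accurate call.
    high_conf_plddt: min mean plDDT for a high-confidence call.
    poor_rmsd: RMSD (Å) above which a model is far from experiment.
    """

    accurate_rmsd: float = 3.0
    accurate_plddt: float = 55.0
    high_conf_plddt: float = 70.0
    poor_rmsd: float = 5.0

    def __post_init__(self) -> None:
        if not self.accurate_rmsd < self.poor_rmsd:
            raise ValidationError("accurate_rmsd must be < poor_rmsd")
        for v in (self.accurate_plddt, self.high_conf_plddt):
            if not 0 <= v <= 100:
                raise ValidationError("plDDT thresholds must lie in [0, 100]")


@dataclass
class ConformationCall:
    """Per-model classification against the two references."""

    label: str  # ground | alternative | neither
    accurate: bool
    high_confidence: bool
    dual: DualRMSD
    plddt: float
    source: str = ""


@dataclass
class ProteinTruth:
    """Which conformations are experimentally confirmed for a protein."""

    observed: frozenset

    def __post_init__(self) -> None:
        self.observed = frozenset(self.observed)
        if not self.observed:
            raise ValidationError("truth must name at least one conformation")
        bad = self.observed - set(CONFORMATIONS)
        if bad:
            raise ValidationError(f"unknown conformations in truth: {sorted(bad)}")


@dataclass
class ProteinCall:
    """Per-protein verdict: which conformations are predicted, and whether
    the protein looks metamorphic or single-folding."""

    predicted: dict[str, bool]
    verdict: str  # metamorphic | single-folder | none
    false_positives: list[ConformationCall]


@dataclass
class EnsembleSummary:
    predicted: dict[str, bool]
    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float
    percent_success: float
    success_rate: float
    n_models: int
    runs: int
    protein: str = ""
    method: str = ""


def classify_model(
    dual: DualRMSD,
    plddt: float,
    th: ClassificationThresholds | None = None,
    source: str = "",
) -> ConformationCall:
    """Label a model ground/alternative/neither and set accuracy flags.

    The label is the conformation with the smaller RMSD provided that RMSD
    is within ``accurate_rmsd``; ties break toward ground with a warning.
    ``accurate`` additionally requires plDDT >= ``accurate_plddt``.
    """
    th = th or ClassificationThresholds()
    if dual.rmsd_ground == dual.rmsd_alt and dual.rmsd_ground <= th.accurate_rmsd:
        logger.warning("equal RMSDs to both references; tie broken toward ground")
        label = GROUND
    elif dual.rmsd_ground <= dual.rmsd_alt and dual.rmsd_ground <= th.accurate_rmsd:
        label = GROUND
    elif dual.rmsd_alt < dual.rmsd_ground and dual.rmsd_alt <= th.accurate_rmsd:
        label = ALTERNATIVE
    else:
        label = NEITHER
    accurate = label != NEITHER and plddt >= th.accurate_plddt
    return ConformationCall(
        label=label,
        accurate=accurate,
        high_confidence=plddt >= th.high_conf_plddt,
        dual=dual,
        plddt=float(plddt),
        source=source,
    )


def detect_false_positives(
    calls: list[ConformationCall],
    truth: ProteinTruth,
    th: ClassificationThresholds | None = None,
) -> list[ConformationCall]:
    """High-confidence calls that contradict experiment: either matching
    neither reference, or matching a conformation not in ``truth.observed``."""
    if not calls:
        raise ParameterError("no calls to screen")
    return [
        c
        for c in calls
        if c.high_confidence
        and (c.label == NEITHER or c.label not in truth.observed)
    ]


def call_protein(
    calls: list[ConformationCall],
    truth: ProteinTruth,
    th: ClassificationThresholds | None = None,
) -> ProteinCall:
    """Protein-level verdict from an ensemble of per-model calls.

    A conformation counts as predicted when at least one call labels it,
    is accurate, and is high-confidence.  Both predicted -> metamorphic;
    exactly one -> single-folder; none -> none.
    """
    if not calls:
        raise ParameterError("no calls to summarize")
    predicted = {
        conf: any(
            c.label == conf and c.accurate and c.high_confidence for c in calls
        )
        for conf in CONFORMATIONS
    }
    n = sum(predicted.values())
    verdict = "metamorphic" if n == 2 else ("single-folder" if n == 1 else "none")
    return ProteinCall(
        predicted=predicted,
        verdict=verdict,
        false_positives=detect_false_positives(calls, truth, th),
    )


def confusion(
    decisions: list[tuple[bool, bool]]
) -> tuple[int, int, int, int]:
    """Tally (predicted, observed) decisions into (TP, FP, TN, FN)."""
    if not decisions:
        raise ParameterError("no decisions to tally")
    tp = sum(1 for p, o in decisions if p and o)
    fp = sum(1 for p, o in decisions if p and not o)
    tn = sum(1 for p, o in decisions if not p and not o)
    fn = sum(1 for p, o in decisions if not p and o)
    return tp, fp, tn, fn


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews Correlation Coefficient of a 2x2 confusion table.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Degenerate
    tables (a zero marginal) return 1.0 when the table is error-free
    (FP = FN = 0 with at least one correct decision) and 0.0 otherwise.
    """
    total = tp + fp + tn + fn
    if total <= 0:
        raise ParameterError("empty confusion table")
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        if fp == 0 and fn == 0 and (tp + tn) > 0:
            return 1.0
        return 0.0
    return (tp * tn - fp * fn) / denom


@dataclass
class SuccessRate:
    """A success percentage at full precision plus the rounded display form."""

    percent: float
    n_accurate: int
    n_models: int

    @property
    def label(self) -> str:
        return f"{round(self.percent)}%"


def success_rate(n_accurate: int, n_models: int) -> SuccessRate:
    """Percentage of accurately predicted models, e.g. 10/250 -> 4.0%."""
    if n_models <= 0:
        raise ParameterError("n_models must be > 0")
    if not 0 <= n_accurate <= n_models:
        raise ParameterError("need 0 <= n_accurate <= n_models")
    return SuccessRate(
        percent=100.0 * n_accurate / n_models,
        n_accurate=n_accurate,
        n_models=n_models,
    )


def runs_accounting(manifest: list[dict]) -> int:
    """Distinct prediction runs contributing to an ensemble.

    Each manifest record may carry a ``run_id``; records without one count
    as their own run (keyed by file name or list position).
    """
    runs = set()
    for i, rec in enumerate(manifest):
        runs.add(rec.get("run_id", rec.get("file", i)))
    return len(runs)


def summarize_ensemble(
    calls: list[ConformationCall],
    truth: ProteinTruth,
    th: ClassificationThresholds | None = None,
    runs: int = 1,
    protein: str = "",
    method: str = "",
) -> EnsembleSummary:
    """Ensemble-level statistics: confusion counts over the two
    (protein, conformation) decisions, MCC, %success, and the per-model
    success rate."""
    pc = call_protein(calls, truth, th)
    decisions = [
        (pc.predicted[conf], conf in truth.observed) for conf in CONFORMATIONS
    ]
    tp, fp, tn, fn = confusion(decisions)
    n_models = len(calls)
    rate = success_rate(sum(1 for c in calls if c.accurate), n_models)
    return EnsembleSummary(
        predicted=pc.predicted,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        mcc=mcc(tp, fp, tn, fn),
        percent_success=100.0 * (tp + tn) / (tp + fp + tn + fn),
        success_rate=rate.percent,
        n_models=n_models,
        runs=runs,
        protein=protein,
        method=method,
    )
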