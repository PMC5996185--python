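"""Therapeutic scoring of drugs and ROC evaluation of labelled drug sets.

A drug's score is the signed agreement between its quantified action vector
and the sign pattern of the optimal stabilizing control, normalized so that
+1 means every action matches and -1 means every action opposes::

    T_d = sum_i u_d[i] * s[i]  /  sum_i |u_d[i]| * |s[i]|

The numerator is signed (so opposing actions decrement the score and
anti-therapeutic drugs come out negative); the denominator uses absolute
values.  A drug with no action on any gene the control touches has
denominator 0 and an UNDEFINED score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .drug_treatment import TreatmentVector

__all__ = [
    "TherapeuticScore",
    "RocResult",
    "therapeutic_score",
    "rank_drugs",
    "roc_auc",
]

logger = logging.getLogger(__name__)


@dataclass
class TherapeuticScore:
    """A drug's normalized agreement score; ``t_d is None`` means UNDEFINED."""

    drug: str
    set_label: str
    t_d: float | None
    numerator: float
    denominator: float
    n_targets_in_model: int = 0

    def __post_init__(self) -> None:
        if self.denominator < 0:
            raise ValueError("denominator must be nonnegative")
        if self.denominator == 0 and self.t_d is not None:
            raise ValueError("score must be UNDEFINED when the denominator is 0")
        if self.denominator > 0 and self.t_d is None:
            raise ValueError("score is only UNDEFINED when the denominator is 0")
        if self.t_d is not None and abs(self.t_d) > 1 + 1e-9:
            raise ValueError(f"|T_d| > 1 for drug {self.drug!r}: {self.t_d}")

    @property
    def is_defined(self) -> bool:
        return self.t_d is not None


@dataclass
class RocResult:
    """All-pairs AUC (ties count half) with the stepwise ROC curve."""

    auc: float
    n_positive: int
    n_negative: int
    curve: list[tuple[float, float]]


def therapeutic_score(
    u_d: TreatmentVector,
    sign_u0: np.ndarray,
    abs_numerator: bool = False,
) -> TherapeuticScore:
    """Score one drug vector against the control's sign pattern.

    ``abs_numerator=True`` wraps the numerator in absolute value, collapsing
    therapeutic and anti-therapeutic drugs onto [0, 1]; the default signed
    numerator distinguishes them.
    """
    vec = np.asarray(u_d.u_d, dtype=float)
    sign = np.asarray(sign_u0, dtype=float)
    if vec.shape != sign.shape:
        raise ValueError(
            f"length mismatch: u_d has {vec.shape}, sign pattern has {sign.shape}"
        )
    numerator = float(vec @ sign)
    if abs_numerator:
        numerator = abs(numerator)
    denominator = float(np.abs(vec) @ np.abs(sign))
    t_d = numerator / denominator if denominator > 0 else None
    return TherapeuticScore(
        drug=u_d.drug,
        set_label=u_d.set_label,
        t_d=t_d,
        numerator=numerator,
        denominator=denominator,
        n_targets_in_model=u_d.n_targets_in_model,
    )


def rank_drugs(scores: list[TherapeuticScore]) -> list[TherapeuticScore]:
    """Sort descending by score; UNDEFINED last; ties broken by drug name."""

    def key(score: TherapeuticScore):
        if score.t_d is None:
            return (1, 0.0, score.drug)
        return (0, -score.t_d, score.drug)

    return sorted(scores, key=key)


def roc_auc(scores: list[TherapeuticScore]) -> RocResult:
    """Separation of positive (D1) from negative (D2) drugs by score.

    AUC is the Mann-Whitney pair statistic: over all D1 x D2 pairs, the
    fraction won by the D1 drug, with ties counting one half.  UNDEFINED
    scores are excluded with a warning; any other set label is ignored.
    """
    dropped = [s for s in scores if s.set_label in ("D1", "D2") and not s.is_defined]
    if dropped:
        logger.warning(
            "excluding %d UNDEFINED scores from ROC: %s",
            len(dropped), [s.drug for s in dropped],
        )
    positives = [s.t_d for s in scores if s.set_label == "D1" and s.is_defined]
    negatives = [s.t_d for s in scores if s.set_label == "D2" and s.is_defined]
    if not positives or not negatives:
        raise ValueError(
            f"ROC needs both classes, got {len(positives)} D1 and {len(negatives)} D2"
        )
    wins = ties = 0
    for pos in positives:
        for neg in negatives:
            if pos > neg:
                wins += 1
            elif pos == neg:
                ties += 1
    auc = (wins + 0.5 * ties) / (len(positives) * len(negatives))
    return RocResult(
        auc=auc,
        n_positive=len(positives),
        n_negative=len(negatives),
        curve=_roc_curve(positives, negatives),
    )


def _roc_curve(positives: list[float], negatives: list[float]) -> list[tuple[float, float]]:
    """Stepwise (FPR, TPR) points from (0, 0) to (1, 1), thresholds descending."""
    n_pos, n_neg = len(positives), len(negatives)
    labelled = [(v, 1) for v in positives] + [(v, 0) for v in negatives]
    labelled.sort(key=lambda pair: -pair[0])
    curve = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(labelled):
        threshold = labelled[i][0]
        # consume the whole tie group at this threshold in one step
        while i < len(labelled) and labelled[i][0] == threshold:
            if labelled[i][1] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        curve.append((fp / n_neg, tp / n_pos))
    if curve[-1] != (1.0, 1.0):  # pragma: no cover - defensive
        curve.append((1.0, 1.0))
    return curve
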