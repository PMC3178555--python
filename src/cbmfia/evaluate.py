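"""Evaluation: confusion counts, ROC curves and corpus summary statistics.

Assesses the HAR flank score as a sequence-based ligand-binding-residue
predictor: residue sites with known binding function form the positive set,
aromatics without experimental annotation the negative set (which inevitably
contains undiscovered binders, so raw false-positive rates are upper bounds).
Also provides the corpus-level alignment and template-usage summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

from .core import ValidationError
from .fia import PairwiseAlignment
from .model_select import ModelCandidate

Site = Hashable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


@dataclass
class RocCurve:
    """(threshold, counts) points covering every distinct score value."""

    points: list[tuple[float, ConfusionCounts]]

    def fpr_tpr(self) -> tuple[np.ndarray, np.ndarray]:
        fpr = np.array([c.fpr for _, c in self.points])
        tpr = np.array([c.tpr for _, c in self.points])
        order = np.lexsort((tpr, fpr))
        return fpr[order], tpr[order]

    def auc(self) -> float:
        """Area under the curve by the trapezoid rule."""
        fpr, tpr = self.fpr_tpr()
        return float(np.trapezoid(tpr, fpr))


def _check_sets(
    scores: Mapping[Site, float], positives: set, negatives: set
) -> None:
    overlap = positives & negatives
    if overlap:
        raise ValidationError(f"positive and negative sets overlap: {sorted(overlap)!r:.80s}")
    missing = (positives | negatives) - set(scores)
    if missing:
        raise ValidationError(f"sites without a score: {sorted(missing)!r:.80s}")


def confusion_at_threshold(
    scores: Mapping[Site, float],
    positives: set,
    negatives: set,
    threshold: float,
) -> ConfusionCounts:
    """Counts with the prediction rule "positive iff score >= threshold"."""
    _check_sets(scores, positives, negatives)
    tp = sum(1 for s in positives if scores[s] >= threshold)
    fp = sum(1 for s in negatives if scores[s] >= threshold)
    return ConfusionCounts(
        tp=tp, fp=fp, tn=len(negatives) - fp, fn=len(positives) - tp
    )


def roc_curve(
    scores: Mapping[Site, float], positives: set, negatives: set
) -> RocCurve:
    """ROC points at every distinct score plus a sentinel above the maximum.

    The lowest threshold predicts every site positive ((fpr, tpr) = (1, 1));
    the sentinel predicts none ((0, 0)).  Points are sorted by threshold.
    """
    if not positives or not negatives:
        raise ValidationError("ROC needs non-empty positive and negative sets")
    _check_sets(scores, positives, negatives)
    used = sorted({scores[s] for s in positives | negatives})
    thresholds = used + [used[-1] + 1]
    return RocCurve(
        points=[
            (t, confusion_at_threshold(scores, positives, negatives, t))
            for t in thresholds
        ]
    )


def binding_prediction_rates(
    templates: Sequence,
    threshold: int = 97,
) -> dict:
    """TP/FP rates of HAR scoring as a binding-residue predictor.

    Builds the evaluation sets from annotated structure templates: aromatic
    sites listed in ``known_binding_positions`` are positives, all other
    aromatic sites negatives, each scored with the default flank weight
    table.  Returns rates (percent) and the underlying counts.  Applied to a
    curated template-profile table this reproduces the corpus-level TP/FP
    percentages; on synthetic data it reports the generator's own rates.
    """
    from .har import har_score

    scores: dict[tuple[str, int], int] = {}
    positives: set = set()
    negatives: set = set()
    for rec in templates:
        residues = rec.sequence.residues
        for pos, res in enumerate(residues, start=1):
            if res not in "WYF":
                continue
            key = (rec.template_id, pos)
            scores[key] = har_score(residues, pos)
            if pos in rec.known_binding_positions:
                positives.add(key)
            else:
                negatives.add(key)
    if not positives or not negatives:
        raise ValidationError("templates provide no positives or no negatives")
    counts = confusion_at_threshold(scores, positives, negatives, threshold)
    curve = roc_curve(scores, positives, negatives)
    return {
        "threshold": threshold,
        "n_positives": len(positives),
        "n_negatives": len(negatives),
        "tp_rate_pct": 100.0 * counts.tpr,
        "fp_rate_pct": 100.0 * counts.fpr,
        "auc": curve.auc(),
    }


def summarize_alignment_stats(alignments: Sequence[PairwiseAlignment]) -> dict:
    """Mean/median percent identity and similarity over an alignment batch."""
    if not alignments:
        raise ValidationError("no alignments to summarize")
    ident = np.array([100.0 * a.ident / a.n_columns for a in alignments])
    sim = np.array([100.0 * a.sim / a.n_columns for a in alignments])
    return {
        "n_alignments": len(alignments),
        "mean_identity_pct": float(ident.mean()),
        "median_identity_pct": float(np.median(ident)),
        "mean_similarity_pct": float(sim.mean()),
        "median_similarity_pct": float(np.median(sim)),
    }


def summarize_template_usage(
    ranked_sets: Sequence[Sequence[ModelCandidate]],
) -> dict:
    """Share of single- vs double-template entries across per-target top lists."""
    if not ranked_sets:
        raise ValidationError("no ranked candidate lists to summarize")
    n_single = n_double = 0
    for ranked in ranked_sets:
        if len(ranked) > 5:
            raise ValidationError("each list must contain at most 5 candidates")
        for cand in ranked:
            if cand.origin == "double":
                n_double += 1
            else:
                n_single += 1
    total = n_single + n_double
    if total == 0:
        raise ValidationError("ranked candidate lists are all empty")
    return {
        "n_targets": len(ranked_sets),
        "n_entries": total,
        "pct_single": 100.0 * n_single / total,
        "pct_double": 100.0 * n_double / total,
    }
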