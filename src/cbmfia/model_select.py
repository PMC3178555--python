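"""Model-candidate enumeration, scoring and selection.

From the filtered candidate set CA, build the candidate simulated-structure
set CSS: every single template plus every unordered pair of templates
(n + n(n-1)/2 candidates).  Triples and larger combinations are excluded;
their cost grows combinatorially while double templates already capture the
useful "main skeleton + compatible/complementary partner" pattern.

Each candidate is scored by a pluggable :data:`StructureScorer` returning a
surface-potential z score (lower = better); the minimum-z candidate is the
selected model s*.  Coordinate building itself is delegated to external
engines via PIR export — the scorer contract lets real (Modeller + potential
energy) z scores be injected from a table, while the deterministic
:func:`mock_surface_scorer` keeps the full pipeline testable offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .core import GAP, AnnotatedSequence, TemplateRecord, ValidationError
from .fia import PairwiseAlignment
from .template_filter import CandidateAlignmentSet

logger = logging.getLogger(__name__)

#: Contract: (target, candidate) -> finite z score, deterministic per input.
StructureScorer = Callable[[AnnotatedSequence, "ModelCandidate"], float]


@dataclass
class ModelCandidate:
    """A single- or double-template modeling candidate."""

    alignments: tuple[PairwiseAlignment, ...]
    z_score: Optional[float] = None
    failed: bool = False

    def __post_init__(self) -> None:
        if len(self.alignments) not in (1, 2):
            raise ValidationError("a candidate uses one or two templates")
        ids = [a.template_id for a in self.alignments]
        if len(set(ids)) != len(ids):
            raise ValidationError("double candidate must use two distinct templates")

    @property
    def template_ids(self) -> tuple[str, ...]:
        return tuple(a.template_id for a in self.alignments)

    @property
    def templates(self) -> tuple[Optional[TemplateRecord], ...]:
        return tuple(a.template for a in self.alignments)

    @property
    def origin(self) -> str:
        return "single" if len(self.alignments) == 1 else "double"

    @property
    def candidate_id(self) -> str:
        return "+".join(self.template_ids)


def enumerate_candidates(ca: CandidateAlignmentSet) -> list[ModelCandidate]:
    """All single and unordered-double candidates from CA, in rank order.

    Singles come first in CA member order, then pairs (i, j), i < j, in the
    same order — deterministic and exhaustive: n + n(n-1)/2 candidates.
    """
    if not ca.members:
        raise ValidationError("candidate alignment set is empty")
    singles = [ModelCandidate(alignments=(a,)) for a in ca.members]
    doubles = [
        ModelCandidate(alignments=(ca.members[i], ca.members[j]))
        for i in range(len(ca.members))
        for j in range(i + 1, len(ca.members))
    ]
    return singles + doubles


def mock_surface_scorer(
    target: AnnotatedSequence, candidate: ModelCandidate
) -> float:
    """Deterministic offline stand-in for a structure-quality z score.

    Per alignment: 1 - 2*(ident / n_columns) - 0.5*(fraction of the target's
    HAR positions aligned onto a template's known binding residues), averaged
    over the candidate's one or two alignments.  Lower is better; the range
    is [-1.5, 1.0].  Candidates whose alignments recover more identity and
    map HARs onto annotated binding sites score lower, mimicking how a real
    surface-potential assessment favours well-templated models.
    """
    if not candidate.alignments:
        raise ValidationError("candidate has no alignments")
    har_positions = {
        i + 1 for i, flag in enumerate(target.track.har_flags) if flag
    }
    values = []
    for aln in candidate.alignments:
        ident_frac = aln.ident / aln.n_columns if aln.n_columns else 0.0
        coverage = 0.0
        if har_positions and aln.template is not None:
            binding = aln.template.known_binding_positions
            hit = sum(
                1
                for tpos, ppos in aln.aligned_pairs()
                if tpos in har_positions and ppos is not None and ppos in binding
            )
            coverage = hit / len(har_positions)
        values.append(1.0 - 2.0 * ident_frac - 0.5 * coverage)
    return sum(values) / len(values)


def table_scorer(z_by_candidate: dict[str, float]) -> StructureScorer:
    """Scorer that injects externally computed z scores keyed by candidate id.

    Use this to feed back real modeling-engine assessments; a missing key
    raises, which :func:`rank_candidates` records as a failed candidate.
    """

    def scorer(target: AnnotatedSequence, candidate: ModelCandidate) -> float:
        return z_by_candidate[candidate.candidate_id]

    return scorer


def rank_candidates(
    target: AnnotatedSequence,
    candidates: Iterable[ModelCandidate],
    scorer: StructureScorer = mock_surface_scorer,
    n_runs: int = 1,
) -> list[ModelCandidate]:
    """Score every candidate and return them sorted by ascending z score.

    A scorer exception marks that candidate failed and excludes it from the
    ranking; the run continues (one bad template must not abort a batch).
    ``n_runs > 1`` averages repeated scorer calls, for scorers with internal
    stochasticity.
    """
    scored: list[ModelCandidate] = []
    for cand in candidates:
        try:
            values = [scorer(target, cand) for _ in range(n_runs)]
            cand.z_score = sum(values) / len(values)
            scored.append(cand)
        except Exception as exc:
            cand.failed = True
            logger.warning(
                "scorer failed for target %s candidate %s: %s",
                target.id,
                cand.candidate_id,
                exc,
            )
    scored.sort(key=lambda c: (c.z_score, len(c.alignments), c.candidate_id))
    return scored


def select_best(ranked: Sequence[ModelCandidate]) -> ModelCandidate:
    """The candidate with minimal z score (ties: fewer templates, then id)."""
    scored = [c for c in ranked if c.z_score is not None and not c.failed]
    if not scored:
        raise ValidationError("no successfully scored candidate to select from")
    return min(scored, key=lambda c: (c.z_score, len(c.alignments), c.candidate_id))
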