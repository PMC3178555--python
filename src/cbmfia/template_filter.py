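"""Template filtering by identity level and similarity level.

Plain percent identity over-rewards gappy alignments, which later translate
into poor model geometry, so the filter statistics charge each opening gap:

    identity_level   = 100 * (ident - gamma * gap_openings) / n_columns
    similarity_level = 100 * (sim   - gamma * gap_openings) / n_columns

The candidate alignment set CA is the union of the top-k alignments under
each statistic; its size is therefore always between k and 2k when the pool
has at least 2k members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .core import ValidationError
from .fia import PairwiseAlignment

Denominator = Literal["columns", "min_length"]


def _denominator(aln: PairwiseAlignment, denominator: Denominator) -> int:
    if denominator == "columns":
        return aln.n_columns
    t_len = len(aln.t_row.replace("-", ""))
    p_len = len(aln.p_row.replace("-", ""))
    return min(t_len, p_len)


def identity_level(
    aln: PairwiseAlignment,
    gamma: float = 1.0,
    denominator: Denominator = "columns",
) -> float:
    """Gap-charged percent identity; may be negative for gappy alignments."""
    if gamma < 0:
        raise ValidationError("gamma must be non-negative")
    return 100.0 * (aln.ident - gamma * aln.gap_openings) / _denominator(aln, denominator)


def similarity_level(
    aln: PairwiseAlignment,
    gamma: float = 1.0,
    denominator: Denominator = "columns",
) -> float:
    """Gap-charged percent similarity (positive substitution-matrix pairs)."""
    if gamma < 0:
        raise ValidationError("gamma must be non-negative")
    return 100.0 * (aln.sim - gamma * aln.gap_openings) / _denominator(aln, denominator)


@dataclass
class CandidateAlignmentSet:
    """The filtered candidate set CA with per-member provenance.

    provenance maps template_id to a subset of {"identity", "similarity"}
    recording which top-k ranking(s) admitted the member.
    """

    k: int
    members: list[PairwiseAlignment]
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aln in self.members:
            if not self.provenance.get(aln.template_id):
                raise ValidationError(
                    f"member {aln.template_id!r} lacks a provenance flag"
                )

    def __len__(self) -> int:
        return len(self.members)


def select_candidates(
    pool: Sequence[PairwiseAlignment],
    k: int = 5,
    gamma: float = 1.0,
    denominator: Denominator = "columns",
) -> CandidateAlignmentSet:
    """Union of the top-k alignments by identity level and by similarity level.

    Ties within either ranking are broken by higher raw alignment score, then
    lexicographic template id, making the selection deterministic.  Members
    are ordered by identity-level rank with similarity-only members appended
    in similarity-level rank order.  If ``k`` exceeds the pool size, the whole
    pool is returned with a warning.
    """
    if not pool:
        raise ValidationError("alignment pool is empty")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(pool):
        warnings.warn(
            f"k={k} exceeds pool size {len(pool)}; returning the entire pool",
            stacklevel=2,
        )
        k = len(pool)

    def ranked(level_fn):
        return sorted(
            pool,
            key=lambda a: (-level_fn(a, gamma, denominator), -a.score, a.template_id),
        )

    top_il = ranked(identity_level)[:k]
    top_sl = ranked(similarity_level)[:k]

    provenance: dict[str, set[str]] = {}
    for aln in top_il:
        provenance.setdefault(aln.template_id, set()).add("identity")
    for aln in top_sl:
        provenance.setdefault(aln.template_id, set()).add("similarity")

    members = list(top_il)
    seen = {a.template_id for a in top_il}
    for aln in top_sl:
        if aln.template_id not in seen:
            members.append(aln)
            seen.add(aln.template_id)

    return CandidateAlignmentSet(
        k=k,
        members=members,
        provenance={tid: frozenset(flags) for tid, flags in provenance.items()},
    )
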