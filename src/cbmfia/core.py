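"""Core domain types shared by every pipeline stage.

The objects here model what flows through the CBM modeling front end: plain
protein sequences, their per-residue feature tracks (3-state secondary
structure, optional confidences, HAR flags), and annotated structure
templates with experimentally known ligand-binding residue positions.

All residue coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Residues treated as candidate ligand-binding aromatics.
AROMATIC = frozenset("WYF")
SS_STATES = frozenset("HEL")
GAP = "-"

_VALID_RESIDUES = frozenset(AA20) | {"X"}


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with optional domain coordinates in its parent.

    Parameters
    ----------
    id:
        Record identifier (FASTA header word, UniProt accession, ...).
    residues:
        Uppercase one-letter amino-acid string; 'X' allowed for unknowns.
    domain_start, domain_end:
        Optional 1-based inclusive coordinates of this domain within the
        full-length parent protein (e.g. a CBM at positions 511-606).
    """

    id: str
    residues: str
    domain_start: Optional[int] = None
    domain_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            pos = next(i + 1 for i, c in enumerate(self.residues) if c in bad)
            raise ValidationError(
                f"sequence {self.id!r}: illegal residue {self.residues[pos - 1]!r} "
                f"at position {pos}"
            )
        if (self.domain_start is None) != (self.domain_end is None):
            raise ValidationError(
                f"sequence {self.id!r}: domain_start/domain_end must be set together"
            )
        if self.domain_start is not None and self.domain_start > self.domain_end:
            raise ValidationError(
                f"sequence {self.id!r}: domain_start {self.domain_start} > "
                f"domain_end {self.domain_end}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(
                f"position {pos} outside [1, {len(self.residues)}] in {self.id!r}"
            )
        return self.residues[pos - 1]


@dataclass
class FeatureTrack:
    """Per-residue features: secondary structure, confidence, HAR flags.

    states holds one of H (helix), E (strand), L (loop) per residue.  The
    invariant "confidence < 0.5 implies loop" mirrors the relabeling applied
    when low-confidence helix/strand predictions are demoted to loop.
    """

    states: str
    confidences: Optional[tuple[float, ...]] = None
    har_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.states) - SS_STATES
        if bad:
            raise ValidationError(f"unknown secondary-structure state(s) {sorted(bad)}")
        if not self.har_flags:
            self.har_flags = [False] * len(self.states)
        if len(self.har_flags) != len(self.states):
            raise ValidationError("har_flags length does not match states")
        if self.confidences is not None:
            self.confidences = tuple(self.confidences)
            if len(self.confidences) != len(self.states):
                raise ValidationError("confidences length does not match states")
            for c, s in zip(self.confidences, self.states):
                if not 0.0 <= c <= 1.0:
                    raise ValidationError(f"confidence {c} outside [0, 1]")
                if c < 0.5 and s != "L":
                    raise ValidationError(
                        "state with confidence < 0.5 must be relabeled to loop"
                    )

    def __len__(self) -> int:
        return len(self.states)

    @classmethod
    def all_loop(cls, length: int) -> "FeatureTrack":
        return cls(states="L" * length)


@dataclass
class AnnotatedSequence:
    """A sequence together with its feature track; the unit of alignment."""

    seq: ProteinSequence
    track: FeatureTrack

    def __post_init__(self) -> None:
        if len(self.track) != len(self.seq):
            raise ValidationError(
                f"{self.seq.id!r}: track length {len(self.track)} != "
                f"sequence length {len(self.seq)}"
            )

    @classmethod
    def plain(cls, seq: ProteinSequence) -> "AnnotatedSequence":
        """Wrap a bare sequence with an all-loop, no-HAR track."""
        return cls(seq=seq, track=FeatureTrack.all_loop(len(seq)))

    @property
    def id(self) -> str:
        return self.seq.id

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TemplateRecord:
    """A structure template: sequence, features and known binding residues.

    known_binding_positions are 1-based positions of aromatic residues with
    experimental evidence of carbohydrate binding; they seed both the
    feature-aware alignment and the evaluation positives.
    """

    template_id: str
    family: str
    sequence: ProteinSequence
    track: FeatureTrack
    known_binding_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if len(self.track) != len(self.sequence):
            raise ValidationError(
                f"template {self.template_id!r}: track/sequence length mismatch"
            )
        self.known_binding_positions = frozenset(self.known_binding_positions)
        for pos in sorted(self.known_binding_positions):
            if not 1 <= pos <= len(self.sequence):
                raise ValidationError(
                    f"template {self.template_id!r}: binding position {pos} outside "
                    f"[1, {len(self.sequence)}]"
                )
            res = self.sequence.residue(pos)
            if res not in AROMATIC:
                raise ValidationError(
                    f"template {self.template_id!r}: binding position {pos} is "
                    f"{res!r}, not an aromatic residue (W/Y/F)"
                )

    @property
    def annotated(self) -> AnnotatedSequence:
        return AnnotatedSequence(seq=self.sequence, track=self.track)


def site(protein_id: str, pos: int) -> tuple[str, int]:
    """Canonical identifier of a residue site: (protein id, 1-based position)."""
    return (protein_id, pos)
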