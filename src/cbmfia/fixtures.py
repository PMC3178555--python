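"""Synthetic CBM-like benchmark generation.

Real CBM corpora pair a small set of solved structure templates with many
unsolved target sequences at low (<30%) identity.  This module emulates that
regime offline: templates are random sequences with planted high-scoring
aromatic binding motifs (flanks drawn from the top-weight residues, so every
planted centre scores >= 97 under the default table) and block-structured
secondary-structure tracks; targets are derived from templates by seeded
substitution/indel mutation that never touches the planted motif windows,
plus secondary-structure state flips emulating imperfect structure
prediction.  Every generator is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_formats
from .core import AA20, AnnotatedSequence, FeatureTrack, ProteinSequence, TemplateRecord
from .har import identify_hars

#: Flank residues used in planted binding motifs: the five heaviest table
#: entries (G, N, S, T, D), so any 4-flank combination scores >= 132.
_MOTIF_FLANKS = "GNSTD"
_CENTRES = "WYF"
_FAMILIES = ("CBM20", "CBM6", "CBM13", "CBM32", "CBM4", "CBM21", "CBM34")

#: Default per-state flip rate for target tracks, emulating ~70% 3-state
#: secondary-structure prediction accuracy.
DEFAULT_SS_FLIP_RATE = 0.3


@dataclass(frozen=True)
class MutationRecord:
    source_template_id: str
    sub_rate: float
    indel_rate: float


@dataclass
class SyntheticBenchmark:
    """Targets, templates and the ground truth linking them."""

    targets: list[AnnotatedSequence]
    templates: list[TemplateRecord]
    truth: dict[str, MutationRecord]
    planted_hars: dict[str, list[int]] = field(default_factory=dict)


def _protected_indices(centres: Sequence[int], length: int) -> frozenset[int]:
    """0-based indices of the 5-residue windows around planted centres."""
    idx = set()
    for c in centres:  # c is 1-based
        for k in range(c - 3, c + 2):
            if 0 <= k < length:
                idx.add(k)
    return frozenset(idx)


def generate_template_set(
    n: int,
    length: int = 100,
    n_binding: int = 3,
    seed: int = 0,
) -> list[TemplateRecord]:
    """Random templates with ``n_binding`` planted binding motifs each.

    Motifs are non-overlapping 5-residue windows (two heavy flanks, a W/Y/F
    centre, two heavy flanks); centres become known_binding_positions.
    Secondary-structure tracks are strand-rich run sequences, mimicking the
    beta-sandwich folds that dominate CBM families.
    """
    if n_binding * 5 > length:
        raise ValueError(
            f"cannot pack {n_binding} 5-residue motifs into length {length}"
        )
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA20))
    templates = []
    for i in range(n):
        residues = rng.choice(aa, size=length)
        # one motif per equal-width segment keeps windows disjoint
        centres = []
        if n_binding:
            seg = length // n_binding
            for b in range(n_binding):
                lo, hi = b * seg + 2, min((b + 1) * seg, length) - 3
                centre = int(rng.integers(lo, hi + 1))  # 0-based
                window = "".join(rng.choice(list(_MOTIF_FLANKS), size=4))
                motif = window[:2] + rng.choice(list(_CENTRES)) + window[2:]
                residues[centre - 2: centre + 3] = list(motif)
                centres.append(centre + 1)
        seq = ProteinSequence(id=f"tmpl{i:03d}", residues="".join(residues))
        track = FeatureTrack(states=_random_track(rng, length))
        record = TemplateRecord(
            template_id=seq.id,
            family=_FAMILIES[i % len(_FAMILIES)],
            sequence=seq,
            track=track,
            known_binding_positions=frozenset(centres),
        )
        identify_hars(record.annotated)  # populate har_flags
        templates.append(record)
    return templates


def _random_track(rng: np.random.Generator, length: int) -> str:
    states = []
    while len(states) < length:
        state = rng.choice(list("ELH"), p=[0.5, 0.4, 0.1])
        run = int(rng.integers(4, 13))
        states.extend([state] * run)
    return "".join(states[:length])


def _mutate(
    residues: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    protected: frozenset[int],
) -> tuple[str, dict[int, int]]:
    """Apply substitutions/indels outside ``protected`` 0-based indices.

    Returns the mutated string and a 1-based map old position -> new
    position for residues that survive.
    """
    out: list[str] = []
    pos_map: dict[int, int] = {}
    aa = list(AA20)
    i, length = 0, len(residues)
    while i < length:
        if i not in protected and indel_rate and rng.random() < indel_rate:
            size = min(int(rng.geometric(0.5)), 5)
            if rng.random() < 0.5:
                # deletion, stopping short of any protected window
                deleted = 0
                while deleted < size and i < length and i not in protected:
                    i += 1
                    deleted += 1
                continue
            out.extend(rng.choice(aa, size=size))
        c = residues[i]
        if i not in protected and sub_rate and rng.random() < sub_rate:
            choices = [x for x in aa if x != c]
            c = choices[int(rng.integers(len(choices)))]
        pos_map[i + 1] = len(out) + 1
        out.append(c)
        i += 1
    return "".join(out), pos_map


def mutate_sequence(
    seq: ProteinSequence,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    preserve_motifs: bool = True,
    motif_centres: Sequence[int] = (),
) -> ProteinSequence:
    """Seeded point-substitution + short-indel mutant of ``seq``.

    With ``preserve_motifs`` the 5-residue windows around ``motif_centres``
    (1-based) are exempt from all edits.  Indel lengths are geometric
    (p = 0.5) capped at 5.
    """
    if not 0 <= sub_rate < 1 or not 0 <= indel_rate < 1:
        raise ValueError("mutation rates must lie in [0, 1)")
    protected = (
        _protected_indices(motif_centres, len(seq)) if preserve_motifs else frozenset()
    )
    rng = np.random.default_rng(seed)
    mutated, _ = _mutate(seq.residues, sub_rate, indel_rate, rng, protected)
    return ProteinSequence(id=f"{seq.id}_mut", residues=mutated)


def _derive_target(
    template: TemplateRecord,
    target_id: str,
    sub_rate: float,
    indel_rate: float,
    ss_flip_rate: float,
    rng: np.random.Generator,
) -> tuple[AnnotatedSequence, list[int]]:
    centres = sorted(template.known_binding_positions)
    protected = _protected_indices(centres, len(template.sequence))
    mutated, pos_map = _mutate(
        template.sequence.residues, sub_rate, indel_rate, rng, protected
    )
    seq = ProteinSequence(id=target_id, residues=mutated)

    # carry the template's states through the position map; insertions -> loop
    states = ["L"] * len(mutated)
    for old, new in pos_map.items():
        states[new - 1] = template.track.states[old - 1]
    if ss_flip_rate:
        for k in range(len(states)):
            if rng.random() < ss_flip_rate:
                states[k] = "HEL".replace(states[k], "")[int(rng.integers(2))]
    ann = AnnotatedSequence(seq=seq, track=FeatureTrack(states="".join(states)))
    identify_hars(ann)
    new_centres = [pos_map[c] for c in centres if c in pos_map]
    return ann, new_centres


def generate_benchmark(
    n_templates: int = 5,
    n_targets_per_template: int = 2,
    divergence_levels: Sequence[float] = (0.3, 0.5, 0.7),
    seed: int = 0,
    length: int = 100,
    n_binding: int = 3,
    indel_rate: float = 0.02,
    ss_flip_rate: float = DEFAULT_SS_FLIP_RATE,
) -> SyntheticBenchmark:
    """Full benchmark: templates plus mutated targets with truth mapping.

    Target j of each template uses substitution rate
    ``divergence_levels[j % len(divergence_levels)]``.
    """
    if n_templates < 1 or n_targets_per_template < 1:
        raise ValueError("counts must be >= 1")
    templates = generate_template_set(
        n_templates, length=length, n_binding=n_binding, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    targets: list[AnnotatedSequence] = []
    truth: dict[str, MutationRecord] = {}
    planted: dict[str, list[int]] = {}
    for template in templates:
        for j in range(n_targets_per_template):
            sub_rate = divergence_levels[j % len(divergence_levels)]
            target_id = f"{template.template_id}_t{j}"
            ann, centres = _derive_target(
                template, target_id, sub_rate, indel_rate, ss_flip_rate, rng
            )
            targets.append(ann)
            truth[target_id] = MutationRecord(
                source_template_id=template.template_id,
                sub_rate=float(sub_rate),
                indel_rate=float(indel_rate),
            )
            planted[target_id] = centres
    return SyntheticBenchmark(
        targets=targets, templates=templates, truth=truth, planted_hars=planted
    )


def generate_corpus(
    templates: Sequence[TemplateRecord],
    n_targets: int,
    divergence_levels: Sequence[float] = (0.3, 0.5, 0.7),
    seed: int = 0,
    indel_rate: float = 0.02,
    ss_flip_rate: float = DEFAULT_SS_FLIP_RATE,
) -> list[AnnotatedSequence]:
    """An arbitrary number of targets cycling over the given templates.

    Used for corpus-scale runs whose target count is not a multiple of the
    template count.
    """
    rng = np.random.default_rng(seed)
    targets = []
    for i in range(n_targets):
        template = templates[i % len(templates)]
        sub_rate = divergence_levels[i % len(divergence_levels)]
        ann, _ = _derive_target(
            template, f"target{i:04d}", sub_rate, indel_rate, ss_flip_rate, rng
        )
        targets.append(ann)
    return targets


def write_benchmark(benchmark: SyntheticBenchmark, outdir) -> None:
    """Write targets (FASTA + track files), templates and truth to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta([t.seq for t in benchmark.targets], outdir / "targets.fasta")
    tracks = outdir / "tracks"
    tracks.mkdir(exist_ok=True)
    for target in benchmark.targets:
        io_formats.write_secstruct_track(target.track, tracks / f"{target.id}.track")
    io_formats.write_template_table(benchmark.templates, outdir / "templates.csv")
    io_formats.write_json(
        {
            tid: {
                "source_template_id": rec.source_template_id,
                "sub_rate": rec.sub_rate,
                "indel_rate": rec.indel_rate,
                "planted_hars": benchmark.planted_hars.get(tid, []),
            }
            for tid, rec in benchmark.truth.items()
        },
        outdir / "truth.json",
    )
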