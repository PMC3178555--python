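"""Readers and writers for every on-disk artifact.

Formats handled here:

* FASTA protein sequences (Biopython SeqIO underneath).
* A two-line secondary-structure track file: a state string over {H, E, L}
  ('C' accepted as loop synonym) and an optional comma-separated confidence
  line.  Helix/strand states predicted with confidence < 0.5 are relabeled
  to loop on read.
* A delimited template-profile table (template_id, family, sequence,
  known_binding_positions, optional sec_struct column).
* PIR alignment export in the dialect homology-modeling engines consume:
  template entries typed ``structureX``, the target typed ``sequence``, all
  rows padded to a common column count and terminated by ``*``.
* TSV/JSON report helpers.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    GAP,
    AnnotatedSequence,
    FeatureTrack,
    FormatError,
    ProteinSequence,
    TemplateRecord,
    ValidationError,
)
from .fia import PairwiseAlignment
from .har import HarCall

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> list[ProteinSequence]:
    """Read protein sequences; uppercased, '*' and whitespace stripped."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        residues = str(rec.seq).upper().replace("*", "").replace(" ", "")
        try:
            out.append(ProteinSequence(id=rec.id, residues=residues))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Secondary-structure tracks

def relabel_low_confidence(states: str, confidences: Optional[Sequence[float]]) -> str:
    """Demote helix/strand states with confidence < 0.5 to loop.

    Idempotent; absent confidences are treated as confident predictions.
    """
    if confidences is None:
        return states
    return "".join(
        "L" if c < 0.5 else s for s, c in zip(states, confidences)
    )


def read_secstruct_track(path: PathLike, seq: ProteinSequence) -> FeatureTrack:
    """Read a two-line track file and validate it against ``seq``."""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty track file")
    states = lines[0].upper().replace("C", "L")
    bad = set(states) - set("HEL")
    if bad:
        raise FormatError(f"{path}: unknown state character(s) {sorted(bad)}")
    if len(states) != len(seq):
        raise ValidationError(
            f"{path}: track length {len(states)} != sequence length "
            f"{len(seq)} for {seq.id!r}"
        )
    confidences: Optional[tuple[float, ...]] = None
    if len(lines) > 1:
        try:
            confidences = tuple(float(x) for x in lines[1].split(","))
        except ValueError as exc:
            raise FormatError(f"{path}: malformed confidence line") from exc
        if len(confidences) != len(seq):
            raise ValidationError(
                f"{path}: {len(confidences)} confidences for "
                f"{len(seq)} residues"
            )
    states = relabel_low_confidence(states, confidences)
    return FeatureTrack(states=states, confidences=confidences)


def write_secstruct_track(track: FeatureTrack, path: PathLike) -> None:
    lines = [track.states]
    if track.confidences is not None:
        lines.append(",".join(f"{c:g}" for c in track.confidences))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Template profile tables

_TEMPLATE_COLUMNS = ["template_id", "family", "sequence", "known_binding_positions"]


def read_template_table(path: PathLike) -> list[TemplateRecord]:
    """Read a CSV/TSV template-profile table into validated records.

    Required columns: template_id, family, sequence, known_binding_positions
    (semicolon-separated 1-based integers, may be empty).  An optional
    sec_struct column carries the 3-state track; absent, an all-loop track
    is assumed.
    """
    text = Path(path).read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    if reader.fieldnames is None or not set(_TEMPLATE_COLUMNS) <= set(reader.fieldnames):
        raise FormatError(
            f"{path}: expected columns {_TEMPLATE_COLUMNS}, got {reader.fieldnames}"
        )
    records = []
    for row in reader:
        tid = row["template_id"].strip()
        raw = (row["known_binding_positions"] or "").strip()
        positions = frozenset(int(p) for p in raw.split(";") if p.strip())
        seq = ProteinSequence(id=tid, residues=row["sequence"].strip().upper())
        ss = (row.get("sec_struct") or "").strip().upper().replace("C", "L")
        track = (
            FeatureTrack(states=ss) if ss else FeatureTrack.all_loop(len(seq))
        )
        try:
            records.append(
                TemplateRecord(
                    template_id=tid,
                    family=row["family"].strip(),
                    sequence=seq,
                    track=track,
                    known_binding_positions=positions,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {tid!r}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no template records")
    return records


def write_template_table(records: Iterable[TemplateRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TEMPLATE_COLUMNS + ["sec_struct"])
        for rec in records:
            writer.writerow(
                [
                    rec.template_id,
                    rec.family,
                    rec.sequence.residues,
                    ";".join(str(p) for p in sorted(rec.known_binding_positions)),
                    rec.track.states,
                ]
            )


# ---------------------------------------------------------------------------
# PIR export

def _slots(aln: PairwiseAlignment) -> tuple[list[str], list[str]]:
    """Decompose an alignment into insertion slots around target residues.

    Returns (inserts, paired): ``inserts[i]`` holds the template residues
    aligned to gaps in the target immediately before target residue i+1
    (slot L holds trailing insertions); ``paired[i]`` is the template
    character aligned to target residue i+1.
    """
    t_len = len(aln.t_row.replace(GAP, ""))
    inserts = ["" for _ in range(t_len + 1)]
    paired = ["" for _ in range(t_len)]
    ti = 0
    for a, b in zip(aln.t_row, aln.p_row):
        if a == GAP:
            inserts[ti] += b
        else:
            paired[ti] = b
            ti += 1
    return inserts, paired


def _merged_rows(
    target: ProteinSequence, alignments: Sequence[PairwiseAlignment]
) -> tuple[str, list[str]]:
    """Project 1-2 pairwise alignments onto a shared column space.

    Insertions from different alignments occupy distinct columns (alignment
    order), so each pairwise alignment is exactly recoverable from the
    merged rows.
    """
    decomposed = [_slots(a) for a in alignments]
    t_cols: list[str] = []
    p_cols: list[list[str]] = [[] for _ in alignments]
    for i in range(len(target) + 1):
        for k, (inserts, _) in enumerate(decomposed):
            for ch in inserts[i]:
                t_cols.append(GAP)
                for kk in range(len(alignments)):
                    p_cols[kk].append(ch if kk == k else GAP)
        if i < len(target):
            t_cols.append(target.residues[i])
            for k, (_, paired) in enumerate(decomposed):
                p_cols[k].append(paired[i])
    return "".join(t_cols), ["".join(c) for c in p_cols]


def _pir_entry(name: str, kind: str, row: str, start: int, end: int) -> str:
    wrapped = "\n".join(row[i: i + 60] for i in range(0, len(row), 60))
    return (
        f">P1;{name}\n"
        f"{kind}:{name}:{start}::{end}:::::\n"
        f"{wrapped}*\n"
    )


def write_pir(
    target: ProteinSequence,
    alignments: Union[PairwiseAlignment, Sequence[PairwiseAlignment]],
    path: PathLike,
) -> None:
    """Write a candidate's alignment(s) as a PIR file for a modeling engine.

    Template entries are typed ``structureX`` and the target ``sequence``.
    With two templates the two pairwise alignments are re-projected onto a
    shared column space so that all rows have equal length.
    """
    if isinstance(alignments, PairwiseAlignment):
        alignments = [alignments]
    if not 1 <= len(alignments) <= 2:
        raise ValidationError("write_pir accepts one or two alignments")
    for aln in alignments:
        if aln.t_row.replace(GAP, "") != target.residues:
            raise ValidationError(
                f"alignment {aln.template_id!r} does not align target "
                f"{target.id!r} (target rows inconsistent)"
            )
    t_row, p_rows = _merged_rows(target, alignments)
    entries = []
    for aln, row in zip(alignments, p_rows):
        length = len(row.replace(GAP, ""))
        entries.append(_pir_entry(aln.template_id, "structureX", row, 1, length))
    start = target.domain_start or 1
    end = target.domain_end or len(target)
    entries.append(_pir_entry(target.id, "sequence", t_row, start, end))
    Path(path).write_text("\n".join(entries))


def read_pir(path: PathLike) -> list[tuple[str, str]]:
    """Parse a PIR file into (id, aligned row) pairs (round-trip checks)."""
    records = list(SeqIO.parse(str(path), "pir"))
    if not records:
        raise FormatError(f"{path}: no PIR entries")
    return [(rec.id, str(rec.seq)) for rec in records]


# ---------------------------------------------------------------------------
# Reports

def har_calls_frame(calls_by_seq: dict[str, list[HarCall]]) -> pd.DataFrame:
    rows = [
        {
            "sequence_id": sid,
            "position": c.position,
            "residue": c.residue,
            "window": c.window,
            "score": c.score,
            "is_har": c.is_har,
        }
        for sid, calls in calls_by_seq.items()
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["sequence_id", "position", "residue", "window", "score", "is_har"]
    )


def alignments_frame(alignments: Iterable[PairwiseAlignment]) -> pd.DataFrame:
    rows = [
        {
            "target_id": a.target_id,
            "template_id": a.template_id,
            "score": a.score,
            "ident": a.ident,
            "sim": a.sim,
            "gap_openings": a.gap_openings,
            "n_columns": a.n_columns,
        }
        for a in alignments
    ]
    return pd.DataFrame(
        rows,
        columns=["target_id", "template_id", "score", "ident", "sim",
                 "gap_openings", "n_columns"],
    )


def write_tsv(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
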