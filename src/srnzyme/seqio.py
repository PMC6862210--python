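"""Reading and validation of protein sequences and class annotations.

Sequences live on a 21-letter amino-acid alphabet (the 20 standard residues
plus ``X`` for any undetermined residue).  Class labels are either an EC
``class.subclass`` string (first digit 1-7) or the literal ``non-enzyme``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("srnzyme")

#: The 21-letter amino-acid alphabet (20 standard residues + X).
ALPHABET = "ARNDCQEGHILKMFPSTWYVX"

_ALPHABET_SET = frozenset(ALPHABET)

#: Ambiguity / non-standard codes folded into X on input.
NONSTANDARD = frozenset("BZJUO*")

#: literal label for sequences without enzymatic activity
NON_ENZYME = "non-enzyme"

_CLASS_RE = re.compile(r"^[1-7]\.[1-9][0-9]*$")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: identifier plus residues over :data:`ALPHABET`."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains letters outside the "
                f"21-letter alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ClassAnnotation:
    """Maps a sequence id to an EC ``class.subclass`` string or ``non-enzyme``."""

    sequence_id: str
    class_id: str

    def __post_init__(self) -> None:
        if not is_valid_class_id(self.class_id):
            raise ValueError(
                f"invalid class id {self.class_id!r} for sequence "
                f"{self.sequence_id!r}: expected 'c.s' with c in 1..7 or "
                f"'{NON_ENZYME}'"
            )

    @property
    def is_enzyme(self) -> bool:
        return self.class_id != NON_ENZYME


def is_valid_class_id(class_id: str) -> bool:
    """True for ``"c.s"`` with c in 1..7 and s a positive integer, or ``non-enzyme``."""
    return class_id == NON_ENZYME or bool(_CLASS_RE.match(class_id))


def normalise_residues(raw: str, record_id: str = "?") -> tuple[str, int]:
    """Upper-case, strip whitespace and fold non-standard letters to X.

    Returns the cleaned residue string and the number of letters mapped to X.
    """
    cleaned = "".join(raw.split()).upper()
    n_mapped = sum(1 for c in cleaned if c in NONSTANDARD)
    if n_mapped:
        cleaned = "".join("X" if c in NONSTANDARD else c for c in cleaned)
    bad = set(cleaned) - _ALPHABET_SET
    if bad:
        raise ValueError(
            f"record {record_id!r} contains unrecognised letters {sorted(bad)}"
        )
    return cleaned, n_mapped


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    Residues are upper-cased; whitespace inside sequence lines is removed;
    non-standard letters (B, Z, J, U, O, ``*``) are mapped to X and the total
    number of substitutions is logged as a warning.

    Raises
    ------
    ValueError
        For an empty file or a record with an empty sequence.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out: list[ProteinSequence] = []
    total_mapped = 0
    for rec in records:
        raw = str(rec.seq)
        if not raw.strip():
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        residues, n_mapped = normalise_residues(raw, rec.id)
        total_mapped += n_mapped
        out.append(ProteinSequence(id=rec.id, residues=residues))
    if total_mapped:
        logger.warning(
            "%d non-standard residue letters mapped to X while reading %s",
            total_mapped,
            path,
        )
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as multi-line FASTA (inverse of :func:`read_fasta`)."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_annotations(path: str | Path) -> list[ClassAnnotation]:
    """Read a two-column TSV (``sequence_id``, ``class_id``) of annotations.

    The first line must be the header ``sequence_id<TAB>class_id``.  Malformed
    class strings and duplicate sequence ids raise ``ValueError`` with the
    offending line number.
    """
    path = Path(path)
    annotations: list[ClassAnnotation] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"empty annotation file {path}") from None
        if [h.strip() for h in header] != ["sequence_id", "class_id"]:
            raise ValueError(
                f"{path}:1: expected header 'sequence_id\\tclass_id', "
                f"got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            seq_id, class_id = row[0].strip(), row[1].strip()
            if not is_valid_class_id(class_id):
                raise ValueError(
                    f"{path}:{lineno}: invalid class id {class_id!r}"
                )
            if seq_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            annotations.append(ClassAnnotation(sequence_id=seq_id, class_id=class_id))
    if not annotations:
        raise ValueError(f"no annotations found in {path}")
    return annotations


def write_annotations(annotations: Iterable[ClassAnnotation], path: str | Path) -> None:
    """Write annotations as the TSV consumed by :func:`read_annotations`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sequence_id", "class_id"])
        for ann in annotations:
            writer.writerow([ann.sequence_id, ann.class_id])


def check_annotations_cover(
    seqs: Sequence[ProteinSequence], annotations: Sequence[ClassAnnotation]
) -> None:
    """Verify every annotation refers to a loaded sequence id."""
    ids = {s.id for s in seqs}
    missing = [a.sequence_id for a in annotations if a.sequence_id not in ids]
    if missing:
        raise ValueError(
            f"annotations refer to unknown sequence ids: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
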