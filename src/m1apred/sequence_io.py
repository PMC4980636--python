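"""FASTA input/output and the window conventions the rest of the package assumes.

All downstream code works on fixed-length RNA windows centered on an
adenosine (the candidate m1A site).  This module is the single gate through
which sequences enter: it normalizes the alphabet (DNA ``T`` -> RNA ``U``,
lowercase -> uppercase), rejects ambiguity codes, and enforces the
odd-length / center-A window invariants.

Positions are 1-based everywhere in messages and outputs; the center of a
length-``l`` window is position ``(l + 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ._errors import (
    AlphabetError,
    DuplicateIdError,
    FastaParseError,
    WindowError,
)

RNA_ALPHABET = frozenset("ACGU")
DEFAULT_WINDOW_LENGTH = 41

Label = Literal["positive", "negative"]

_NORMALIZE = str.maketrans("acgutT", "ACGUUU")


def normalize_sequence(seq: str, *, record_id: str = "<unnamed>") -> str:
    """Uppercase, transliterate T->U, and reject anything outside {A,C,G,U}.

    Idempotent: normalizing a normalized sequence is a no-op.
    """
    out = seq.translate(_NORMALIZE)
    bad = set(out) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"record '{record_id}': invalid character(s) "
            f"{sorted(bad)!r}; only A, C, G, U (or T for DNA input) are allowed"
        )
    return out


@dataclass(frozen=True)
class SequenceRecord:
    """One identified RNA sequence, optionally labeled positive/negative."""

    id: str
    seq: str
    label: Optional[Label] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")

    def with_label(self, label: Optional[Label]) -> "SequenceRecord":
        return SequenceRecord(self.id, self.seq, label)

    def __len__(self) -> int:
        return len(self.seq)


def center_position(window_length: int) -> int:
    """1-based index of the center of an odd-length window."""
    if window_length <= 0 or window_length % 2 == 0:
        raise WindowError(
            f"window length must be an odd positive integer, got {window_length}"
        )
    return (window_length + 1) // 2


def validate_window(
    record: SequenceRecord, window_length: int = DEFAULT_WINDOW_LENGTH
) -> SequenceRecord:
    """Check that ``record`` is a valid adenosine-centered window.

    Returns the record unchanged on success.  This is the gate run before
    encoding and before insertion into a :class:`WindowDataset`.

    Raises
    ------
    WindowError
        If the length differs from ``window_length`` or the center base
        (1-based position ``(window_length + 1) / 2``) is not ``A``.
    """
    c = center_position(window_length)
    if len(record.seq) != window_length:
        raise WindowError(
            f"record '{record.id}': window length is {len(record.seq)}, "
            f"expected {window_length}"
        )
    if record.seq[c - 1] != "A":
        raise WindowError(
            f"record '{record.id}': center base at position {c} is "
            f"'{record.seq[c - 1]}', expected 'A'"
        )
    return record


@dataclass
class WindowDataset:
    """A labeled collection of equal-length adenosine-centered windows.

    ``tag`` carries free-text provenance (species / cell line / synthetic
    condition) and travels into every evaluation report.
    """

    records: list[SequenceRecord] = field(default_factory=list)
    window_length: int = DEFAULT_WINDOW_LENGTH
    tag: str = ""

    def __post_init__(self) -> None:
        for rec in self.records:
            validate_window(rec, self.window_length)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def positives(self) -> list[SequenceRecord]:
        return [r for r in self.records if r.label == "positive"]

    @property
    def negatives(self) -> list[SequenceRecord]:
        return [r for r in self.records if r.label == "negative"]

    def labels(self) -> list[int]:
        """Numeric labels: 1 for positive, 0 for negative."""
        out = []
        for r in self.records:
            if r.label is None:
                raise ValueError(f"record '{r.id}' is unlabeled")
            out.append(1 if r.label == "positive" else 0)
        return out


def read_fasta(path: str | Path, label: Optional[Label] = None) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Wrapped and single-line sequences are both accepted.  Every record is
    normalized (T->U, uppercased) and must contain only A/C/G/U afterwards.
    If ``label`` is given it is assigned to all records.

    Raises
    ------
    FastaParseError, AlphabetError, DuplicateIdError
    """
    path = Path(path)
    _check_fasta_shape(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id '{bio.id}'")
        seen.add(bio.id)
        seq = normalize_sequence(str(bio.seq), record_id=bio.id)
        records.append(SequenceRecord(bio.id, seq, label))
    return records


def _check_fasta_shape(path: Path) -> None:
    """Reject text that is not FASTA (Bio.SeqIO silently yields nothing)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected a '>' header line before "
                    f"sequence data"
                )
            return  # first non-blank line is a header: good enough


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as single-line-sequence FASTA.

    Round-trip property: ``read_fasta`` on the output reproduces the input
    (id, seq) pairs exactly.  Labels are not serialized; they live in the
    dataset manifest.
    """
    bio_records = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(bio_records)
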