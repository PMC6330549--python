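"""Degenerate consensus patterns: derivation, scanning and segment alignment.

Patterns use a compact PROSITE-like dialect: a bare letter is a fixed
position, ``[E/D]`` is an alternative set, and ``-`` is a single-position
wildcard.  Under this reading the peptide REQEIYV matches the consensus
``R[E/D]Q[D/E]-[Y/F/W][L/V]`` exactly.  ``X`` in a sequence is matched by
wildcards only, never by a set position.

Consensus derivation works column-wise over an ungapped alignment block:
a column with one distinct residue emits a fixed letter, a column with at
most ``max_alternatives`` distinct residues emits an alternative set
(ordered by column frequency, then alphabetically), anything more
degenerate emits a wildcard.  Every row of the block matches the derived
pattern by construction.

:func:`align_segment` slides a peptide over a longer target without gaps,
scoring 2 per identity and (optionally) 1 per same polarity class, and is
the basis for transferring interface contacts onto candidate peptides.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .residue_chemistry import classify_letter

__all__ = [
    "SequenceRecord",
    "AlignmentBlock",
    "ConsensusPattern",
    "MotifHit",
    "SegmentAlignment",
    "PatternError",
    "parse_pattern",
    "derive_consensus",
    "scan_sequence",
    "scan_database",
    "align_segment",
    "read_fasta",
    "write_fasta",
]

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
SEQ_ALPHABET = AA_LETTERS | {"X"}


class PatternError(ValueError):
    """Malformed pattern text."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.seq) - SEQ_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: invalid residue letters {sorted(bad)}")


@dataclass(frozen=True)
class AlignmentBlock:
    """Ungapped, equal-length sequence segments with provenance."""

    rows: tuple[str, ...]
    sources: tuple[tuple[str, int], ...] = ()  # (source id, 1-based start)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment block needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment block rows differ in length")
        if any("-" in r or "." in r for r in self.rows):
            raise ValueError("alignment block rows must be ungapped")

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class ConsensusPattern:
    """Ordered positions: a tuple of allowed letters, or None for a wildcard."""

    positions: tuple[Union[tuple[str, ...], None], ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternError("pattern must have at least one position")
        for pos in self.positions:
            if pos is not None and len(pos) == 0:
                raise PatternError("empty alternative set")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def text(self) -> str:
        parts = []
        for pos in self.positions:
            if pos is None:
                parts.append("-")
            elif len(pos) == 1:
                parts.append(pos[0])
            else:
                parts.append("[" + "/".join(pos) + "]")
        return "".join(parts)

    def matches_at(self, seq: str, start: int) -> bool:
        """Position-wise match at 0-based offset ``start``."""
        if start < 0 or start + len(self) > len(seq):
            return False
        for i, pos in enumerate(self.positions):
            ch = seq[start + i]
            if pos is None:
                continue  # wildcard matches anything, including X
            if ch not in pos:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    start: int  # 1-based
    match: str

    @property
    def end(self) -> int:
        return self.start + len(self.match) - 1


def parse_pattern(text: str) -> ConsensusPattern:
    """Parse the PROSITE-like dialect described in the module docstring.

    Bracketed sets require at least two alternatives (a single letter is
    written bare), which makes parse/render a strict round trip.
    """
    if not text:
        raise PatternError("empty pattern")
    positions: list[Union[tuple[str, ...], None]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "-":
            positions.append(None)
            i += 1
        elif ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise PatternError(f"unbalanced bracket at position {i + 1}")
            alts = text[i + 1:end].split("/")
            if any(a == "" for a in alts):
                raise PatternError(f"empty alternative in {text[i:end + 1]!r}")
            if len(alts) < 2:
                raise PatternError(f"set {text[i:end + 1]!r} needs >=2 alternatives; "
                                   "write a single residue bare")
            bad = [a for a in alts if a not in AA_LETTERS]
            if bad:
                raise PatternError(f"invalid residues {bad} in alternative set")
            if len(set(alts)) != len(alts):
                raise PatternError(f"duplicate residues in {text[i:end + 1]!r}")
            positions.append(tuple(alts))
            i = end + 1
        elif ch in AA_LETTERS:
            positions.append((ch,))
            i += 1
        else:
            raise PatternError(f"unexpected character {ch!r} at position {i + 1}")
    return ConsensusPattern(tuple(positions))


def derive_consensus(block: AlignmentBlock, max_alternatives: int = 3) -> ConsensusPattern:
    """Column-wise consensus of an ungapped alignment block.

    Columns containing ``X`` become wildcards (a set may never match X,
    so this is required for every row to match the output).
    """
    positions: list[Union[tuple[str, ...], None]] = []
    for col in range(block.width):
        counts = Counter(row[col] for row in block.rows)
        distinct = set(counts)
        if "X" in distinct or len(distinct) > max_alternatives:
            positions.append(None)
        else:
            ordered = sorted(distinct, key=lambda ch: (-counts[ch], ch))
            positions.append(tuple(ordered))
    return ConsensusPattern(tuple(positions))


def scan_sequence(pattern: ConsensusPattern, record: SequenceRecord) -> list[MotifHit]:
    """All (overlapping) matches of a pattern in one sequence, 1-based starts."""
    hits = []
    n, m = len(record.seq), len(pattern)
    for start in range(n - m + 1):
        if pattern.matches_at(record.seq, start):
            hits.append(MotifHit(record.id, start + 1, record.seq[start:start + m]))
    return hits


RecordsInput = Union[str, Path, io.TextIOBase, Iterable[SequenceRecord]]


def _as_records(records: RecordsInput) -> list[SequenceRecord]:
    if isinstance(records, (str, Path)) or hasattr(records, "read"):
        return read_fasta(records)
    return list(records)


def scan_database(pattern: ConsensusPattern, records: RecordsInput,
                  exclusion: Sequence[ConsensusPattern] = ()) -> list[MotifHit]:
    """Scan a sequence database, dropping records that match any exclusion
    pattern anywhere (e.g. histone-like motifs).  Hit order follows record
    order, then position."""
    hits: list[MotifHit] = []
    for record in _as_records(records):
        if any(scan_sequence(excl, record) for excl in exclusion):
            continue
        hits.extend(scan_sequence(pattern, record))
    return hits


@dataclass(frozen=True)
class SegmentAlignment:
    """Best ungapped placement of a peptide on a target sequence."""

    peptide_id: str
    target_id: str
    offset: int  # 0-based offset of peptide position 1 in the target
    score: int
    labels: tuple[str, ...]  # per peptide position: identity | class | mismatch

    @property
    def target_start(self) -> int:
        """1-based target position aligned to peptide position 1."""
        return self.offset + 1


def _column_score(p: str, t: str, class_aware: bool) -> tuple[int, str]:
    if p == t:
        return 2, "identity"
    if class_aware and p in AA_LETTERS and t in AA_LETTERS \
            and classify_letter(p) == classify_letter(t):
        return 1, "class"
    return 0, "mismatch"


def align_segment(peptide: SequenceRecord, target: SequenceRecord,
                  class_aware: bool = True) -> SegmentAlignment:
    """Slide ``peptide`` over ``target`` without gaps and return the
    maximal-score offset (ties: smallest offset) with per-position labels."""
    if not peptide.seq or not target.seq:
        raise ValueError("empty sequence")
    if len(peptide.seq) > len(target.seq):
        raise ValueError("peptide longer than target")
    best = None
    for off in range(len(target.seq) - len(peptide.seq) + 1):
        score = 0
        labels = []
        for i, p in enumerate(peptide.seq):
            s, lab = _column_score(p, target.seq[off + i], class_aware)
            score += s
            labels.append(lab)
        if best is None or score > best.score:
            best = SegmentAlignment(peptide.id, target.id, off, score, tuple(labels))
    return best


def read_fasta(source: Union[str, Path, io.TextIOBase]) -> list[SequenceRecord]:
    handle = source
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    try:
        out = []
        for rec in SeqIO.parse(handle, "fasta"):
            try:
                out.append(SequenceRecord(rec.id, str(rec.seq).upper(),
                                          rec.description))
            except ValueError as exc:
                raise ValueError(f"unreadable FASTA record {rec.id!r}: {exc}") from exc
        if not out:
            raise ValueError("no FASTA records found")
        return out
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord],
                target: Union[str, Path, io.TextIOBase, None] = None) -> str:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
           for r in records]
    buf = io.StringIO()
    SeqIO.write(bio, buf, "fasta")  # wraps at 60 columns
    text = buf.getvalue()
    if target is not None:
        if isinstance(target, (str, Path)):
            Path(target).write_text(text)
        else:
            target.write(text)
    return text
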