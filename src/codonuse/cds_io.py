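"""Reading, validating and deduplicating coding sequences.

QC mirrors common practice for codon-usage studies: a usable CDS starts
with ATG, ends with one of TAA/TAG/TGA, has length a multiple of 3, and
contains no ambiguity codes; exact-sequence duplicates are dropped.  mRNA
records with UTRs are handled by extracting the longest forward-strand
open reading frame first (``extract_orf``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

START_CODON = "ATG"
STOP_CODONS = ("TAA", "TAG", "TGA")
_VALID_BASES = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised for an empty or malformed FASTA input."""


@dataclass(frozen=True)
class CodingSequence:
    """One nucleotide sequence with identity and provenance.

    The sequence is stored uppercase with U mapped to T.  ``is_validated``
    marks sequences that passed ``validate_cds`` (in-frame ATG..STOP over
    the unambiguous alphabet).
    """

    id: str
    sequence: str
    accession: str | None = None
    is_validated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", self.sequence.upper().replace("U", "T")
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ValidationReport:
    """Disposition of every input record: passed, rejected or duplicate."""

    input_count: int = 0
    passed: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    duplicates_removed: list[str] = field(default_factory=list)

    def check(self) -> None:
        n = len(self.passed) + len(self.rejected) + len(self.duplicates_removed)
        if n != self.input_count:
            raise AssertionError(
                f"report inconsistent: {n} dispositions for "
                f"{self.input_count} inputs"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "passed": self.passed,
                "rejected": [list(r) for r in self.rejected],
                "duplicates_removed": self.duplicates_removed,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["id\tdisposition"]
        lines += [f"{i}\tpassed" for i in self.passed]
        lines += [f"{i}\trejected: {reason}" for i, reason in self.rejected]
        lines += [f"{i}\tduplicate" for i in self.duplicates_removed]
        return "\n".join(lines) + "\n"


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Parse a FASTA file into unvalidated ``CodingSequence`` records.

    The header token before the first whitespace becomes the id (and the
    accession when it looks like a versioned accession).  Raises
    ``FileNotFoundError`` for a missing file and ``FastaFormatError`` for
    an empty file or content that does not start with a FASTA header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise FastaFormatError(f"{path}: empty file")
    if not stripped.startswith(">"):
        first = stripped.splitlines()[0]
        raise FastaFormatError(
            f"{path}: not FASTA — first line {first!r} is not a header"
        )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id if _looks_like_accession(rec.id) else None
        records.append(
            CodingSequence(id=rec.id, sequence=str(rec.seq), accession=accession)
        )
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write sequences as FASTA, 60 characters per line."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def _looks_like_accession(token: str) -> bool:
    head, _, version = token.partition(".")
    return bool(version) and version.isdigit() and "_" in head


def validate_cds(
    seq: CodingSequence,
    require_start: bool = True,
    require_stop: bool = True,
) -> tuple[CodingSequence | None, str | None]:
    """Apply the CDS QC rules; return (validated sequence, None) or (None, reason).

    Rejection reasons: non-ACGT symbol, length not a multiple of 3, missing
    START, missing STOP.  Ambiguity codes (N, R, Y, ...) are rejected rather
    than skipped because every downstream formula assumes unambiguous codons.
    Flags allow skipping the START/STOP checks for partial CDSs.
    """
    s = seq.sequence
    bad = set(s) - _VALID_BASES
    if bad:
        return None, f"non-ACGT symbol ({', '.join(sorted(bad))})"
    if len(s) == 0 or len(s) % 3 != 0:
        return None, f"length {len(s)} not a positive multiple of 3"
    if require_start and s[:3] != START_CODON:
        return None, "missing START (first codon is not ATG)"
    if require_stop and s[-3:] not in STOP_CODONS:
        return None, "missing STOP (last codon not in TAA/TAG/TGA)"
    return replace(seq, is_validated=True), None


def extract_orf(seq: CodingSequence) -> CodingSequence | None:
    """Longest forward-strand ATG..STOP open reading frame, any of frames 0/1/2.

    Used for mRNA records carrying UTRs: codon indices are only meaningful
    on the CDS, while GC% and length are reported on the full record.
    Returns ``None`` when no complete ORF exists.  Coordinates are 0-based
    half-open internally.
    """
    s = seq.sequence
    best: tuple[int, int] | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if start is None:
                if codon == START_CODON:
                    start = i
            elif codon in STOP_CODONS:
                if best is None or (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
    if best is None:
        return None
    return replace(seq, sequence=s[best[0] : best[1]], is_validated=False)


def deduplicate(
    seqs: Sequence[CodingSequence],
) -> tuple[list[CodingSequence], ValidationReport]:
    """Drop exact-sequence duplicates, keeping the first occurrence.

    Duplicate means identical nucleotide string, not identical id.
    """
    seen: dict[str, str] = {}
    kept: list[CodingSequence] = []
    report = ValidationReport(input_count=len(seqs))
    for s in seqs:
        if s.sequence in seen:
            report.duplicates_removed.append(s.id)
        else:
            seen[s.sequence] = s.id
            kept.append(s)
            report.passed.append(s.id)
    report.check()
    return kept, report


def qc_pipeline(
    seqs: Sequence[CodingSequence],
    require_start: bool = True,
    require_stop: bool = True,
    cds_only: bool = False,
) -> tuple[list[CodingSequence], ValidationReport]:
    """Full QC: optional ORF extraction, validation, then deduplication."""
    report = ValidationReport(input_count=len(seqs))
    validated: list[CodingSequence] = []
    for s in seqs:
        candidate = s
        if cds_only:
            orf = extract_orf(s)
            if orf is None:
                report.rejected.append((s.id, "no complete ORF found"))
                continue
            candidate = orf
        ok, reason = validate_cds(candidate, require_start, require_stop)
        if ok is None:
            report.rejected.append((s.id, reason))
        else:
            validated.append(ok)
    seen: set[str] = set()
    kept: list[CodingSequence] = []
    for s in validated:
        if s.sequence in seen:
            report.duplicates_removed.append(s.id)
        else:
            seen.add(s.sequence)
            kept.append(s)
            report.passed.append(s.id)
    report.check()
    return kept, report
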