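"""Reading, cleaning and writing protein sequence cohorts.

Sequences arrive as multi-FASTA files (one file per cohort: the
unconventionally secreted positive set, the conventionally secreted
negative set). Records are cleaned — whitespace, digits and ``*``
terminators stripped, everything uppercased — and residues outside the
20-letter amino-acid alphabet (B, J, O, U, X, Z) are flagged by position
but left in place, so downstream coordinates stay aligned with the input.
Flagged residues never satisfy any motif position, fixed or wildcard.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ucps_motif")

#: the 20 standard amino acids, the alphabet of the motif space
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)

#: ambiguity/rare codes kept in sequences but excluded from motif matching;
#: selenocysteine (U) and pyrrolysine (O) are deliberately nonstandard here
#: because the 20-letter alphabet defines the 8000-motif space
NONSTANDARD_AA = frozenset("BJOUXZ")

COHORTS = ("positive", "negative", "unlabelled")


class ValidationError(ValueError):
    """Raised for malformed sequence input."""


@dataclass
class ProteinRecord:
    """One protein sequence with its cohort label.

    Parameters
    ----------
    id
        First whitespace-delimited token of the FASTA header.
    sequence
        Uppercase amino-acid string (may contain nonstandard letters).
    cohort
        ``"positive"``, ``"negative"`` or ``"unlabelled"``.
    nonstandard_positions
        0-based indices of residues outside the 20 standard amino acids.
    description
        Remainder of the FASTA header after the id token.
    """

    id: str
    sequence: str
    cohort: str = "unlabelled"
    nonstandard_positions: List[int] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if not self.sequence.isupper() or not self.sequence.isalpha():
            raise ValidationError(
                f"record {self.id!r}: sequence must be uppercase A-Z"
            )
        if self.cohort not in COHORTS:
            raise ValidationError(f"record {self.id!r}: unknown cohort {self.cohort!r}")
        n = len(self.sequence)
        if any(i < 0 or i >= n for i in self.nonstandard_positions):
            raise ValidationError(
                f"record {self.id!r}: nonstandard position out of range"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def clean_sequence(raw: str) -> Tuple[str, List[int]]:
    """Normalise a raw sequence string.

    Removes whitespace, digits and ``*`` terminators, uppercases the rest,
    and records the 0-based positions of nonstandard residues
    (B, J, O, U, X, Z). No characters are substituted.

    Returns
    -------
    (sequence, nonstandard_positions)

    Raises
    ------
    ValidationError
        If nothing remains after cleaning, or a non-letter survives.
    """
    kept = []
    for ch in raw:
        if ch.isspace() or ch.isdigit() or ch == "*":
            continue
        kept.append(ch.upper())
    seq = "".join(kept)
    if not seq:
        raise ValidationError("sequence empty after cleaning")
    if not seq.isalpha():
        bad = sorted({c for c in seq if not c.isalpha()})
        raise ValidationError(f"sequence contains non-letter characters: {bad}")
    nonstandard = [i for i, ch in enumerate(seq) if ch in NONSTANDARD_AA]
    return seq, nonstandard


def read_fasta(path: str | Path, cohort: str = "unlabelled") -> List[ProteinRecord]:
    """Read a multi-FASTA file into labelled :class:`ProteinRecord` objects.

    Records keep file order. Duplicate ids receive a deterministic numeric
    suffix (``.2``, ``.3``, ...) with a logged warning. An entry whose
    sequence is empty after cleaning raises :class:`ValidationError` naming
    the offending header.
    """
    path = Path(path)
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    records: List[ProteinRecord] = []
    seen: Counter[str] = Counter()
    for entry in SeqIO.parse(str(path), "fasta"):
        header_id = entry.id
        try:
            seq, nonstd = clean_sequence(str(entry.seq))
        except ValidationError as exc:
            raise ValidationError(f"entry {header_id!r}: {exc}") from exc
        seen[header_id] += 1
        rec_id = header_id
        if seen[header_id] > 1:
            rec_id = f"{header_id}.{seen[header_id]}"
            logger.warning(
                "duplicate FASTA id %r renamed to %r", header_id, rec_id
            )
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(
            ProteinRecord(
                id=rec_id,
                sequence=seq,
                cohort=cohort,
                nonstandard_positions=nonstd,
                description=desc,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to ``path`` as wrapped multi-FASTA."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)
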