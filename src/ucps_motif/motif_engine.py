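"""Motif enumeration, mirror canonicalisation and sequence scanning.

The motif space is all length-k strings over the 20 standard amino acids
(k in {2, 3, 4}): 400, 8000 or 160000 literal motifs. Because a short
linear motif read off a chain has no intrinsic direction at this level of
description, a motif can optionally be identified with its reversal
("mirror symmetry"), which collapses the 3-mer space from 8000 to 4200
equivalence classes — (20^k + 20^ceil(k/2)) / 2 in general.

Patterns extend motifs with single-position wildcards written ``X``
(e.g. ``KKX`` for di-lysine plus any residue, ``WXXL`` for the core
LC3-interacting region). A wildcard matches any of the 20 standard
residues only: a literal ``X`` (or other ambiguity code) in a sequence is
an unknown residue and matches nothing, so nonstandard letters can never
create motif hits.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import List, Sequence

from .sequence_io import STANDARD_AA, STANDARD_AA_SET

ACIDIC = frozenset("DE")

_WILDCARD_CLASS = "[" + STANDARD_AA + "]"
# lookahead so overlapping windows are all reported
_TRIACIDIC_RE = re.compile(r"(?=[DE]{3})")


@dataclass(frozen=True, order=True)
class Span:
    """Half-open interval [start, end) locating one motif hit."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class Pattern:
    """Fixed-length pattern over the 20 amino acids plus ``X`` wildcards.

    At least one position must be fixed. Matching is exact at fixed
    positions; wildcard positions accept any standard residue.
    """

    __slots__ = ("spec", "positions", "_regex")

    def __init__(self, spec: str):
        spec = spec.upper()
        if not spec:
            raise ValueError("empty pattern")
        positions = []
        for ch in spec:
            if ch == "X":
                positions.append(None)  # wildcard
            elif ch in STANDARD_AA_SET:
                positions.append(ch)
            else:
                raise ValueError(f"pattern {spec!r}: invalid character {ch!r}")
        if all(p is None for p in positions):
            raise ValueError(f"pattern {spec!r}: at least one position must be fixed")
        self.spec = spec
        self.positions = tuple(positions)
        self._regex = re.compile(
            "(?=" + "".join(_WILDCARD_CLASS if p is None else p for p in positions) + ")"
        )

    def __len__(self) -> int:
        return len(self.positions)

    def __repr__(self) -> str:
        return f"Pattern({self.spec!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pattern) and self.spec == other.spec

    def __hash__(self) -> int:
        return hash(self.spec)

    def matches_at(self, sequence: str, start: int) -> bool:
        """True if the pattern matches ``sequence`` at offset ``start``."""
        if start < 0 or start + len(self) > len(sequence):
            return False
        for offset, fixed in enumerate(self.positions):
            ch = sequence[start + offset]
            if fixed is None:
                if ch not in STANDARD_AA_SET:
                    return False
            elif ch != fixed:
                return False
        return True


#: the canonical patterns of the analysis
KKX = Pattern("KKX")
WXXL = Pattern("WXXL")

#: extended LIR consensus [W/F/Y]XX[L/I/V] as a union of 9 patterns
EXTENDED_LIR_PATTERNS = tuple(
    Pattern(f"{a}XX{b}") for a in "WFY" for b in "LIV"
)


def validate_motif(m: str) -> str:
    """Uppercase and validate a literal motif (length 2-4, standard AAs)."""
    m = m.upper()
    if not (2 <= len(m) <= 4):
        raise ValueError(f"motif {m!r}: length must be 2-4")
    if any(ch not in STANDARD_AA_SET for ch in m):
        raise ValueError(f"motif {m!r}: only the 20 standard amino acids allowed")
    return m


def canonical_form(m: str) -> str:
    """Mirror-canonical representative: the lexicographic min of m and its reversal."""
    r = m[::-1]
    return m if m <= r else r


def enumerate_motifs(k: int, collapse_mirror: bool = False) -> List[str]:
    """All length-k motifs over the standard alphabet, sorted.

    With ``collapse_mirror`` each {m, reverse(m)} pair is represented once
    by its canonical form; palindromes represent themselves. For k = 3
    this yields 4200 motifs instead of 8000.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"k must be in {{2, 3, 4}}, got {k}")
    motifs = ("".join(t) for t in product(sorted(STANDARD_AA), repeat=k))
    if not collapse_mirror:
        return list(motifs)
    return sorted({canonical_form(m) for m in motifs})


def find_motif_hits(sequence: str, motif: str) -> List[Span]:
    """All (possibly overlapping) exact occurrences of a literal motif."""
    hits = []
    start = sequence.find(motif)
    while start != -1:
        hits.append(Span(start, start + len(motif)))
        start = sequence.find(motif, start + 1)
    return hits


def find_pattern_hits(sequence: str, pattern: Pattern | str) -> List[Span]:
    """All (possibly overlapping) pattern hits, ascending by start."""
    if isinstance(pattern, str):
        pattern = Pattern(pattern)
    k = len(pattern)
    return [
        Span(m.start(), m.start() + k) for m in pattern._regex.finditer(sequence)
    ]


def triacidic_hits(sequence: str) -> List[Span]:
    """All length-3 windows consisting entirely of D/E residues.

    Equivalent to the union of hits of the 8 motifs over {D, E};
    overlapping windows are all reported.
    """
    return [Span(m.start(), m.start() + 3) for m in _TRIACIDIC_RE.finditer(sequence)]


def contains_motif(sequence: str, motif: str, mirror_aware: bool = False) -> bool:
    """Presence test: does the motif (or, mirror-aware, its reversal) occur?"""
    if motif in sequence:
        return True
    if mirror_aware:
        return motif[::-1] in sequence
    return False


def sequence_kmer_set(sequence: str, k: int, mirror: bool = False) -> set:
    """Set of distinct standard-alphabet k-mers present in a sequence.

    Windows containing any nonstandard residue are skipped. With
    ``mirror`` each k-mer is recorded by its canonical form. This is the
    presence primitive of the enrichment analysis: each protein
    contributes each k-mer at most once.
    """
    out = set()
    std = STANDARD_AA_SET
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        if all(ch in std for ch in w):
            out.add(canonical_form(w) if mirror else w)
    return out


def hits_of_class(sequence: str, class_def: "str | Sequence[str | Pattern]") -> List[Span]:
    """Merged, sorted, deduplicated hits of a motif class.

    ``class_def`` is either the name ``"triacidic"``, a pattern/motif
    string, a :class:`Pattern`, or a sequence of those.
    """
    if isinstance(class_def, str):
        members: Sequence = [class_def]
    elif isinstance(class_def, Pattern):
        members = [class_def]
    else:
        members = list(class_def)
    if not members:
        raise ValueError("empty motif class")
    spans = set()
    for member in members:
        if isinstance(member, str) and member.lower() == "triacidic":
            spans.update(triacidic_hits(sequence))
        elif isinstance(member, Pattern):
            spans.update(find_pattern_hits(sequence, member))
        elif isinstance(member, str) and "X" in member.upper():
            spans.update(find_pattern_hits(sequence, Pattern(member)))
        elif isinstance(member, str):
            spans.update(find_motif_hits(sequence, validate_motif(member)))
        else:
            raise TypeError(f"unsupported class member {member!r}")
    return sorted(spans)
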