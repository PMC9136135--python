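"""Sequence-proximity analysis: LIR motifs, motif-motif gaps, S/T/Y context.

The gap between two motif hits is the number of residues strictly
between their spans; overlapping or adjacent spans have gap 0. Two motif
classes are sequence-proximal when the minimum gap over all hit pairs is
at most a threshold (3 residues in the primary analysis, 5 in the
validation set). The phosphorylation-context test asks whether a serine,
threonine or tyrosine lies within a flanking window (default 3 residues)
on either side of a motif hit; residues inside the hit itself are not
counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .motif_engine import (
    EXTENDED_LIR_PATTERNS,
    KKX,
    WXXL,
    Span,
    find_pattern_hits,
    triacidic_hits,
)
from .sequence_io import ProteinRecord

STY = frozenset("STY")


def span_gap(a: Span, b: Span) -> int:
    """Residues strictly between two spans; 0 if they overlap or touch."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def lir_hits(sequence: str, mode: str = "core") -> List[Span]:
    """LC3-interacting-region hits.

    ``core`` scans the WXXL consensus; ``extended`` scans
    [W/F/Y]XX[L/I/V] as the union of the nine corresponding patterns.
    Overlapping hits are all reported, ascending.
    """
    if mode == "core":
        return find_pattern_hits(sequence, WXXL)
    if mode == "extended":
        spans = set()
        for pat in EXTENDED_LIR_PATTERNS:
            spans.update(find_pattern_hits(sequence, pat))
        return sorted(spans)
    raise ValueError(f"unknown LIR mode {mode!r}")


def proximal_pair(
    hitsA: Sequence[Span], hitsB: Sequence[Span], max_gap: int
) -> Optional[Tuple[Tuple[Span, Span], int, bool]]:
    """Closest pair of hits between two classes.

    Returns ``((a, b), min_gap, proximal)`` where ``proximal`` is
    ``min_gap <= max_gap``, or ``None`` when either list is empty.
    Ties resolve to the earliest pair in (a.start, b.start) order.
    """
    if not hitsA or not hitsB:
        return None
    best: Optional[Tuple[Span, Span]] = None
    best_gap = -1
    for a in hitsA:
        for b in hitsB:
            g = span_gap(a, b)
            if best is None or g < best_gap:
                best, best_gap = (a, b), g
    assert best is not None
    return best, best_gap, best_gap <= max_gap


def sty_near_span(sequence: str, span: Span, window: int = 3) -> bool:
    """Is an S/T/Y residue within ``window`` residues of either flank?

    The windows are [start-window, start) and [end, end+window), clipped
    to the sequence; residues inside the span itself are excluded.
    """
    if span.end > len(sequence):
        raise ValueError("span exceeds sequence length")
    lo = max(0, span.start - window)
    for i in range(lo, span.start):
        if sequence[i] in STY:
            return True
    hi = min(len(sequence), span.end + window)
    for i in range(span.end, hi):
        if sequence[i] in STY:
            return True
    return False


def sty_near_any(sequence: str, spans: Sequence[Span], window: int = 3) -> bool:
    """True when any hit in the list has an S/T/Y flank."""
    return any(sty_near_span(sequence, s, window) for s in spans)


@dataclass
class FeatureRecord:
    """All motif-context features of one protein.

    Boolean flags and gap fields are derived from the stored hit lists;
    gap fields are ``None`` when either motif class has no hit.
    """

    protein_id: str
    has_triacidic: bool
    has_kkx: bool
    has_lir: bool
    lir_triacidic_min_gap: Optional[int]
    lir_kkx_min_gap: Optional[int]
    sty_near_triacidic: bool
    sty_near_kkx: bool
    triacidic_spans: List[Span] = field(default_factory=list)
    kkx_spans: List[Span] = field(default_factory=list)
    lir_spans: List[Span] = field(default_factory=list)


def protein_feature_record(
    record: ProteinRecord,
    lir_mode: str = "core",
    gap_threshold: int = 3,
    sty_window: int = 3,
) -> FeatureRecord:
    """Scan one protein for triacidic, KKX and LIR hits and derive features.

    ``gap_threshold`` only affects the proximal flags implied by the gap
    fields downstream; the minimum gaps themselves are stored unthresholded
    so both the 3- and 5-residue readings can be taken from one record.
    """
    seq = record.sequence
    tri = triacidic_hits(seq)
    kkx = find_pattern_hits(seq, KKX)
    lir = lir_hits(seq, mode=lir_mode)

    def min_gap(a, b):
        res = proximal_pair(a, b, gap_threshold)
        return None if res is None else res[1]

    return FeatureRecord(
        protein_id=record.id,
        has_triacidic=bool(tri),
        has_kkx=bool(kkx),
        has_lir=bool(lir),
        lir_triacidic_min_gap=min_gap(lir, tri),
        lir_kkx_min_gap=min_gap(lir, kkx),
        sty_near_triacidic=sty_near_any(seq, tri, sty_window),
        sty_near_kkx=sty_near_any(seq, kkx, sty_window),
        triacidic_spans=tri,
        kkx_spans=kkx,
        lir_spans=lir,
    )


#: fixed column order of the per-protein feature TSV
FEATURE_COLUMNS = [
    "protein_id", "cohort",
    "has_triacidic", "has_kkx", "has_lir",
    "lir_triacidic_min_gap", "lir_kkx_min_gap",
    "sty_near_triacidic", "sty_near_kkx",
    "n_triacidic_hits", "n_kkx_hits", "n_lir_hits",
]


def feature_table(
    records: Sequence[ProteinRecord],
    lir_mode: str = "core",
    gap_threshold: int = 3,
    sty_window: int = 3,
):
    """Per-protein feature DataFrame in the fixed column order."""
    import pandas as pd

    rows = []
    for rec in records:
        fr = protein_feature_record(
            rec, lir_mode=lir_mode, gap_threshold=gap_threshold, sty_window=sty_window
        )
        rows.append(
            {
                "protein_id": fr.protein_id,
                "cohort": rec.cohort,
                "has_triacidic": fr.has_triacidic,
                "has_kkx": fr.has_kkx,
                "has_lir": fr.has_lir,
                "lir_triacidic_min_gap": fr.lir_triacidic_min_gap,
                "lir_kkx_min_gap": fr.lir_kkx_min_gap,
                "sty_near_triacidic": fr.sty_near_triacidic,
                "sty_near_kkx": fr.sty_near_kkx,
                "n_triacidic_hits": len(fr.triacidic_spans),
                "n_kkx_hits": len(fr.kkx_spans),
                "n_lir_hits": len(fr.lir_spans),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
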