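"""Synthetic protein cohorts with planted motif structure, and toy PDB chains.

The generator emulates the statistical design of the real cohorts: two
sets of proteins (positive/negative) in which motif constructs
(triacidic 3-mers, KKX, WXXL, ...) are present in a controlled fraction
of each cohort, optionally co-located within a chosen sequence gap and
optionally flanked by a phosphorylatable S/T/Y residue.

Prevalence is controlled *exactly*: background residues are redrawn
until they contain no spontaneous hit of any planted construct's
detection class, so a construct is present in a protein if and only if
it was planted there. Per-cohort presence counts are therefore exactly
Binomial(n, p), which is what the parameter-recovery tests check.
Plants overwrite background residues (lengths never change), wildcard
positions are drawn from the background distribution, and constraint
satisfaction uses rejection sampling with a bounded retry count.

Reproducibility: one root seed; each protein draws from its own
deterministic substream keyed by (cohort offset + protein index), so
changing one cohort's size never reshuffles the other cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.SeqUtils import seq3

from .motif_engine import ACIDIC, Pattern, Span, find_pattern_hits, triacidic_hits
from .proximity import span_gap, sty_near_span
from .sequence_io import STANDARD_AA, ProteinRecord

_NEGATIVE_STREAM_OFFSET = 1 << 20  # keeps cohort substreams disjoint

#: average vertebrate amino-acid frequencies (UniProt-style composition);
#: opt-in alternative to the uniform default because triacidic/KKX base
#: rates depend strongly on D/E/K abundance
VERTEBRATE_FREQS: Dict[str, float] = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


class GenerationError(RuntimeError):
    """Constraint satisfaction failed within the retry bound."""


@dataclass
class PlantSpec:
    """One construct to plant.

    ``construct`` is a literal motif or a wildcard pattern (``KKX``,
    ``WXXL``); wildcards are materialised from the background
    distribution at plant time. ``detect`` names the class used both to
    suppress spontaneous background hits and to verify the plant:
    by default the triacidic class when the construct is a D/E-only
    3-mer, else the construct pattern itself.
    """

    name: str
    construct: str
    p_pos: float
    p_neg: float
    colocate_with: Optional[str] = None   # name of the partner plant
    max_gap: int = 3
    flank_sty: bool = False
    sty_window: int = 3
    detect: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_pos <= 1.0 and 0.0 <= self.p_neg <= 1.0):
            raise ValueError(f"plant {self.name!r}: probabilities must be in [0, 1]")
        if self.detect is None:
            if len(self.construct) == 3 and set(self.construct) <= ACIDIC:
                self.detect = "triacidic"
            else:
                self.detect = self.construct


@dataclass
class SyntheticParams:
    """Full description of one synthetic study."""

    n_pos: int
    n_neg: int
    length: "int | Tuple[int, int]" = 300
    background: Optional[Dict[str, float]] = None  # None = uniform over 20
    plants: List[PlantSpec] = field(default_factory=list)
    seed: int = 0


@dataclass
class TruthTable:
    """Per-protein record of which constructs were planted where."""

    entries: Dict[str, List[Tuple[str, Span]]] = field(default_factory=dict)

    def spans_for(self, protein_id: str, plant_name: str) -> List[Span]:
        return [s for (n, s) in self.entries.get(protein_id, []) if n == plant_name]

    def planted(self, protein_id: str, plant_name: str) -> bool:
        return bool(self.spans_for(protein_id, plant_name))

    def prevalence(self, ids: Sequence[str], plant_name: str) -> float:
        return sum(self.planted(i, plant_name) for i in ids) / len(ids)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"protein_id": pid, "plant": name, "start": s.start, "end": s.end}
            for pid, items in self.entries.items()
            for (name, s) in items
        ]
        return pd.DataFrame(rows, columns=["protein_id", "plant", "start", "end"])


def _background_arrays(background: Optional[Dict[str, float]]):
    if background is None:
        letters = np.array(list(STANDARD_AA))
        probs = np.full(len(letters), 1.0 / len(letters))
        return letters, probs
    letters = np.array(sorted(background))
    probs = np.array([background[ch] for ch in letters], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("background frequencies must be non-negative and sum > 0")
    if not set(background) <= set(STANDARD_AA):
        raise ValueError("background letters must be standard amino acids")
    return letters, probs / probs.sum()


def _detect_hits(sequence: str, detect: str) -> List[Span]:
    if detect == "triacidic":
        return triacidic_hits(sequence)
    return find_pattern_hits(sequence, Pattern(detect))


def _draw_positions(rng, length: int, k: int, taken: List[Span],
                    partner: Optional[Span], max_gap: int) -> Optional[int]:
    candidates = []
    for start in range(length - k + 1):
        cand = Span(start, start + k)
        if any(span_gap(cand, t) == 0 for t in taken):  # overlap or touching
            continue
        if partner is not None and span_gap(cand, partner) > max_gap:
            continue
        candidates.append(start)
    if not candidates:
        return None
    return int(candidates[rng.integers(len(candidates))])


def generate_protein(
    length: int,
    background: Optional[Dict[str, float]],
    plants: Sequence[Tuple[PlantSpec, bool]],
    rng: np.random.Generator,
    protein_id: str = "synthetic",
    cohort: str = "unlabelled",
    max_retries: int = 500,
) -> Tuple[ProteinRecord, List[Tuple[str, Span]]]:
    """Generate one protein; ``plants`` pairs each spec with its selection flag.

    The returned truth entries list ``(plant name, span)`` for every
    construct actually planted; rescanning the sequence with each
    plant's detection class recovers exactly those spans.
    """
    letters, probs = _background_arrays(background)
    selected = [(spec, sel) for spec, sel in plants]
    # partners must be placed before their dependents
    order = sorted(
        range(len(selected)),
        key=lambda i: (selected[i][0].colocate_with is not None, i),
    )
    for _ in range(max_retries):
        seq_arr = rng.choice(letters, size=length, p=probs)
        truth: List[Tuple[str, Span]] = []
        placed: Dict[str, Span] = {}
        taken: List[Span] = []
        ok = True
        for i in order:
            spec, sel = selected[i]
            if not sel:
                continue
            partner = None
            if spec.colocate_with is not None:
                partner = placed.get(spec.colocate_with)
            k = len(spec.construct)
            start = _draw_positions(rng, length, k, taken, partner, spec.max_gap)
            if start is None:
                ok = False
                break
            span = Span(start, start + k)
            for off, ch in enumerate(spec.construct):
                if ch == "X":
                    ch = str(rng.choice(letters, p=probs))
                seq_arr[start + off] = ch
            taken.append(span)
            placed[spec.name] = span
            truth.append((spec.name, span))
        if not ok:
            continue
        seq = "".join(seq_arr)
        # force an S/T/Y flank where requested, outside any planted span
        for spec, sel in selected:
            if not (sel and spec.flank_sty):
                continue
            span = placed[spec.name]
            if sty_near_span(seq, span, spec.sty_window):
                continue
            flank = [
                j
                for j in list(range(max(0, span.start - spec.sty_window), span.start))
                + list(range(span.end, min(length, span.end + spec.sty_window)))
                if not any(t.start <= j < t.end for t in taken)
            ]
            if not flank:
                ok = False
                break
            j = int(flank[rng.integers(len(flank))])
            seq_arr[j] = str(rng.choice(np.array(["S", "T", "Y"])))
            seq = "".join(seq_arr)
        if not ok:
            continue
        # verify: each detection class hits exactly the planted spans
        expected: Dict[str, set] = {}
        for spec, _sel in selected:
            expected.setdefault(spec.detect, set())
        for (name, span) in truth:
            spec = next(s for s, _ in selected if s.name == name)
            expected[spec.detect].add(span)
        for detect, spans in expected.items():
            if set(_detect_hits(seq, detect)) != spans:
                ok = False
                break
        if ok:
            for spec, sel in selected:
                if sel and spec.flank_sty and not sty_near_span(
                    seq, placed[spec.name], spec.sty_window
                ):
                    ok = False
        if not ok:
            continue
        record = ProteinRecord(id=protein_id, sequence=seq, cohort=cohort)
        return record, truth
    raise GenerationError(
        f"{protein_id}: could not satisfy plant constraints in {max_retries} tries"
    )


def _protein_rng(seed: int, stream_index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(stream_index,)))
    )


def generate_cohorts(
    params: SyntheticParams,
) -> Tuple[List[ProteinRecord], List[ProteinRecord], TruthTable]:
    """Generate both cohorts reproducibly from the root seed.

    Protein ``i`` of a cohort always uses substream ``offset + i``
    (positive offset 0, negative offset 2^20), so the positive cohort is
    byte-identical across runs regardless of ``n_neg`` and vice versa.
    """
    truth = TruthTable()
    cohorts: Dict[str, List[ProteinRecord]] = {"positive": [], "negative": []}
    for cohort, n, offset in (
        ("positive", params.n_pos, 0),
        ("negative", params.n_neg, _NEGATIVE_STREAM_OFFSET),
    ):
        prefix = "pos" if cohort == "positive" else "neg"
        for i in range(n):
            rng = _protein_rng(params.seed, offset + i)
            if isinstance(params.length, int):
                length = params.length
            else:
                lo, hi = params.length
                length = int(rng.integers(lo, hi + 1))
            selections = []
            for spec in params.plants:
                p = spec.p_pos if cohort == "positive" else spec.p_neg
                selections.append((spec, bool(rng.random() < p)))
            pid = f"{prefix}_{i:05d}"
            record, entries = generate_protein(
                length,
                params.background,
                selections,
                rng,
                protein_id=pid,
                cohort=cohort,
            )
            cohorts[cohort].append(record)
            if entries:
                truth.entries[pid] = entries
    return cohorts["positive"], cohorts["negative"], truth


_PDB_ATOM = (
    "ATOM  {serial:>5d}  CA  {res:>3s} A{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           C\n"
)


def straight_chain_pdb(sequence: str, spacing: float = 3.8) -> str:
    """Minimal PDB text: one CA per residue at (i * spacing, 0, 0).

    Chain A, author numbering 1-based. The fixture gives exactly known
    CA-CA distances (``spacing * |i - j|``) for geometry tests.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = sorted({ch for ch in sequence if ch not in STANDARD_AA})
    if bad:
        raise ValueError(f"nonstandard residues not allowed in fixture: {bad}")
    lines = []
    for i, ch in enumerate(sequence):
        lines.append(
            _PDB_ATOM.format(
                serial=i + 1,
                res=seq3(ch).upper(),
                resseq=i + 1,
                x=i * spacing,
                y=0.0,
                z=0.0,
                occ=1.0,
                b=0.0,
            )
        )
    lines.append("TER\nEND\n")
    return "".join(lines)


def write_cohorts(
    pos: Sequence[ProteinRecord],
    neg: Sequence[ProteinRecord],
    truth: TruthTable,
    outdir: str | Path,
) -> Dict[str, Path]:
    """Write FASTA per cohort plus the truth table TSV; returns the paths."""
    from .sequence_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "positive_fasta": outdir / "positive.fasta",
        "negative_fasta": outdir / "negative.fasta",
        "truth_tsv": outdir / "truth.tsv",
    }
    write_fasta(pos, paths["positive_fasta"])
    write_fasta(neg, paths["negative_fasta"])
    truth.to_dataframe().to_csv(paths["truth_tsv"], sep="\t", index=False)
    return paths
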