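"""Structural proximity of motif hits within a PDB chain.

Sequence-level motif hits are mapped onto the residues of a single PDB
chain, and the proximity of two motif classes (e.g. a LIR and a
triacidic motif) is the minimum Euclidean distance over all atom pairs
drawn one from each class's mapped residues. Thresholds of 10 and 15 Å
reproduce the two structural-proximity criteria of the analysis.

Mapping strategy: author residue numbering is assumed 1-based and
aligned to the sequence, accepted wherever the residue identity agrees;
when that covers less than half of the chain (e.g. construct numbering
offsets), an ungapped sliding match of the chain's residue string within
the sequence is attempted instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import cdist

from .motif_engine import Span, hits_of_class
from .proximity import lir_hits

logger = logging.getLogger("ucps_motif")

ATOM_MODES = ("all_heavy", "ca_only")


class MappingError(ValueError):
    """Sequence-to-structure mapping too poor to use."""


class CoverageError(ValueError):
    """A span has no structurally mapped residue."""


@dataclass
class ChainResidue:
    """One residue of a PDB chain with its heavy-atom coordinates."""

    number: int          # author residue number
    resname: str         # 3-letter code
    one_letter: str      # 'X' for unknown codes
    atoms: List[Tuple[str, np.ndarray]]

    def coords(self, atom_mode: str) -> np.ndarray:
        if atom_mode == "ca_only":
            xyz = [c for (name, c) in self.atoms if name == "CA"]
        else:
            xyz = [c for (_, c) in self.atoms]
        return np.array(xyz, dtype=float)


@dataclass
class StructureChain:
    """Ordered residues of one chain plus the sequence-index mapping."""

    chain_id: str
    residues: List[ChainResidue]
    mapping: Dict[int, int] = field(default_factory=dict)  # seq idx -> residue pos

    @property
    def residue_string(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class MappingReport:
    mapped_fraction: float
    method: str                      # "author_numbering" | "sliding"
    unmapped_indices: List[int]      # sequence indices left unmapped
    mapping: Dict[int, int]


def load_chain(
    pdb_path: str | Path, chain_id: str, atom_mode: str = "all_heavy"
) -> StructureChain:
    """Parse one chain of a PDB file (first model only).

    Hydrogens are excluded; for alternate locations the first altloc in
    file order is kept; residues lacking the atoms required by
    ``atom_mode`` are dropped with a warning. Hetero residues (waters,
    ligands) are skipped.
    """
    if atom_mode not in ATOM_MODES:
        raise ValueError(f"atom_mode must be one of {ATOM_MODES}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(pdb_path))
    models = list(structure)
    if not models:
        raise ValueError(f"{pdb_path}: no ATOM records")
    model = models[0]
    if chain_id not in [c.id for c in model]:
        raise LookupError(f"{pdb_path}: chain {chain_id!r} not present")
    residues: List[ChainResidue] = []
    for res in model[chain_id]:
        hetflag, resseq, _icode = res.id
        if hetflag != " ":
            continue
        atoms: List[Tuple[str, np.ndarray]] = []
        seen = set()
        for atom in res.get_unpacked_list():
            if atom.element in ("H", "D"):
                continue
            if atom.get_name() in seen:  # later altlocs ignored
                continue
            seen.add(atom.get_name())
            # PDB coordinates carry exactly 3 decimals; rounding the parser's
            # float32 values back to them keeps distances exact in float64
            coord = np.round(np.asarray(atom.get_coord(), dtype=float), 3)
            atoms.append((atom.get_name(), coord))
        if atom_mode == "ca_only" and "CA" not in seen:
            logger.warning(
                "chain %s residue %s%d lacks CA, dropped", chain_id, res.get_resname(), resseq
            )
            continue
        if not atoms:
            logger.warning(
                "chain %s residue %s%d has no heavy atoms, dropped",
                chain_id, res.get_resname(), resseq,
            )
            continue
        if not np.all(np.isfinite(np.vstack([c for _, c in atoms]))):
            raise ValueError(f"{pdb_path}: non-finite coordinates in residue {resseq}")
        residues.append(
            ChainResidue(
                number=resseq,
                resname=res.get_resname(),
                one_letter=protein_letters_3to1.get(res.get_resname(), "X"),
                atoms=atoms,
            )
        )
    if not residues:
        raise ValueError(f"{pdb_path}: chain {chain_id!r} has no usable ATOM records")
    return StructureChain(chain_id=chain_id, residues=residues)


def map_spans(sequence: str, chain: StructureChain) -> MappingReport:
    """Align sequence indices to chain residues; stores the map on the chain.

    Author numbering ``n`` maps sequence index ``n - 1`` when the residue
    identities agree. When fewer than half of the chain residues map that
    way, an exact ungapped match of the chain's residue string inside the
    sequence is tried. Below 50% coverage the structure is unusable for
    this sequence and :class:`MappingError` is raised.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n_chain = len(chain.residues)
    direct: Dict[int, int] = {}
    for pos, res in enumerate(chain.residues):
        idx = res.number - 1
        if 0 <= idx < len(sequence) and res.one_letter == sequence[idx]:
            direct[idx] = pos
    if len(direct) / n_chain >= 0.5:
        mapping, method = direct, "author_numbering"
    else:
        mapping, method = {}, "sliding"
        chain_str = chain.residue_string
        for offset in range(len(sequence) - n_chain + 1):
            if sequence[offset : offset + n_chain] == chain_str:
                mapping = {offset + pos: pos for pos in range(n_chain)}
                break
    fraction = len(mapping) / n_chain
    if fraction < 0.5:
        raise MappingError(
            f"only {fraction:.0%} of chain {chain.chain_id!r} residues map to the "
            "sequence; structure unusable"
        )
    chain.mapping = mapping
    unmapped = [i for i in range(len(sequence)) if i not in mapping]
    return MappingReport(
        mapped_fraction=fraction, method=method,
        unmapped_indices=unmapped, mapping=dict(mapping),
    )


def _span_coords(chain: StructureChain, span: Span, atom_mode: str) -> np.ndarray:
    blocks = []
    for idx in range(span.start, span.end):
        pos = chain.mapping.get(idx)
        if pos is not None:
            c = chain.residues[pos].coords(atom_mode)
            if c.size:
                blocks.append(c)
    if not blocks:
        raise CoverageError(f"span [{span.start}, {span.end}) has no mapped residue")
    return np.vstack(blocks)


def min_span_distance(
    chain: StructureChain, spanA: Span, spanB: Span, atom_mode: str = "all_heavy"
) -> float:
    """Minimum atom-atom distance (Å) between two mapped spans.

    Requires :func:`map_spans` to have been run on the chain. Symmetric
    in its span arguments; raises :class:`CoverageError` when a span has
    no mapped residue.
    """
    if atom_mode not in ATOM_MODES:
        raise ValueError(f"atom_mode must be one of {ATOM_MODES}")
    a = _span_coords(chain, spanA, atom_mode)
    b = _span_coords(chain, spanB, atom_mode)
    return float(cdist(a, b).min())


def _class_hits(sequence: str, class_def) -> List[Span]:
    if isinstance(class_def, str) and class_def.lower() in ("lir", "lir_core"):
        return lir_hits(sequence, mode="core")
    if isinstance(class_def, str) and class_def.lower() == "lir_extended":
        return lir_hits(sequence, mode="extended")
    if isinstance(class_def, (list, tuple)) and class_def and isinstance(class_def[0], Span):
        return list(class_def)
    return hits_of_class(sequence, class_def)


def structural_proximity_flag(
    chain: StructureChain,
    sequence: str,
    classA,
    classB,
    threshold: float,
    atom_mode: str = "all_heavy",
) -> Tuple[bool, float, Tuple[Span, Span]]:
    """Minimum 3D distance between two motif classes, with a threshold flag.

    ``classA``/``classB`` accept class names (``"triacidic"``, ``"kkx"``,
    ``"lir"``, ``"lir_extended"``), motif/pattern strings or lists, or
    precomputed span lists. Returns ``(flag, min_distance, best_pair)``
    where ``flag`` is ``min_distance <= threshold``. Span pairs with no
    mapped residues are ignored; if no pair is measurable a
    :class:`CoverageError` is raised.
    """
    hitsA = _class_hits(sequence, classA)
    hitsB = _class_hits(sequence, classB)
    if not hitsA:
        raise CoverageError(f"no hits for class {classA!r} in sequence")
    if not hitsB:
        raise CoverageError(f"no hits for class {classB!r} in sequence")
    best: Optional[Tuple[Span, Span]] = None
    best_d = np.inf
    measurable = False
    for a in hitsA:
        for b in hitsB:
            try:
                d = min_span_distance(chain, a, b, atom_mode=atom_mode)
            except CoverageError:
                continue
            measurable = True
            if d < best_d:
                best_d, best = d, (a, b)
    if not measurable or best is None:
        raise CoverageError("no hit pair of the two classes is structurally mapped")
    return best_d <= threshold, best_d, best
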