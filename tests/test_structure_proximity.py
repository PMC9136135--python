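import math

import numpy as np
import pytest

from ucps_motif import (
    CoverageError,
    MappingError,
    Span,
    load_chain,
    map_spans,
    min_span_distance,
    straight_chain_pdb,
    structural_proximity_flag,
)
from ucps_motif.structure_proximity import ChainResidue, StructureChain


@pytest.fixture
def straight(tmp_path):
    """Straight CA chain with a LIR and a triacidic motif, CA every 3.8 A."""
    seq = "MWEELAAAAADEEKAAAAAK"
    p = tmp_path / "straight.pdb"
    p.write_text(straight_chain_pdb(seq))
    chain = load_chain(p, "A", atom_mode="ca_only")
    map_spans(seq, chain)
    return seq, chain


def offset_pdb(tmp_path, seq, first_number):
    text = straight_chain_pdb(seq)
    out = []
    for line in text.splitlines(keepends=True):
        if line.startswith("ATOM"):
            old = int(line[22:26])
            line = line[:22] + f"{old + first_number - 1:>4}" + line[26:]
        out.append(line)
    p = tmp_path / "offset.pdb"
    p.write_text("".join(out))
    return p


class TestLoadChain:
    def test_roundtrip_straight_chain(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(straight_chain_pdb("MDEEK"))
        chain = load_chain(p, "A", atom_mode="ca_only")
        assert len(chain.residues) == 5
        assert chain.residue_string == "MDEEK"
        assert chain.residues[0].number == 1
        np.testing.assert_allclose(chain.residues[4].coords("ca_only"), [[15.2, 0, 0]])

    def test_absent_chain_is_lookup_error(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(straight_chain_pdb("MDEEK"))
        with pytest.raises(LookupError):
            load_chain(p, "Z")

    def test_only_first_model_loaded(self, tmp_path):
        body = straight_chain_pdb("MDEEK").replace("END\n", "ENDMDL\n")
        two_models = (
            "MODEL        1\n" + body
            + "MODEL        2\n" + straight_chain_pdb("MDEEKAA").replace("END\n", "ENDMDL\n")
            + "END\n"
        )
        p = tmp_path / "two.pdb"
        p.write_text(two_models)
        chain = load_chain(p, "A", atom_mode="ca_only")
        assert len(chain.residues) == 5

    def test_no_atoms_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(ValueError):
            load_chain(p, "A")


class TestMapSpans:
    def test_author_numbering(self, tmp_path):
        seq = "MDEEK"
        p = tmp_path / "t.pdb"
        p.write_text(straight_chain_pdb(seq))
        chain = load_chain(p, "A", atom_mode="ca_only")
        report = map_spans(seq, chain)
        assert report.mapped_fraction == 1.0
        assert report.method == "author_numbering"
        assert sorted(report.mapping) == [0, 1, 2, 3, 4]

    def test_offset_numbering_falls_back_to_sliding(self, tmp_path):
        core = "DEEKAWEELK"
        seq = "MMMMM" + core + "GGGGG"
        p = offset_pdb(tmp_path, core, first_number=101)
        chain = load_chain(p, "A", atom_mode="ca_only")
        report = map_spans(seq, chain)
        assert report.method == "sliding"
        assert report.mapped_fraction == 1.0
        assert report.mapping[5] == 0  # core starts at sequence index 5

    def test_unrelated_chain_is_mapping_error(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(straight_chain_pdb("WWWWW"))
        chain = load_chain(p, "A", atom_mode="ca_only")
        with pytest.raises(MappingError):
            map_spans("MDEEKMDEEK", chain)


class TestMinSpanDistance:
    def test_straight_chain_arithmetic(self, straight):
        seq, chain = straight
        # closest CA pair between residues {0-2} and {10-12} is 2 vs 10
        d = min_span_distance(chain, Span(0, 3), Span(10, 13), "ca_only")
        assert d == pytest.approx(3.8 * 8, abs=1e-9)

    def test_identical_spans_are_zero(self, straight):
        _, chain = straight
        assert min_span_distance(chain, Span(0, 3), Span(0, 3), "ca_only") == 0.0

    def test_unmapped_span_is_coverage_error(self, straight):
        seq, chain = straight
        with pytest.raises(CoverageError):
            min_span_distance(chain, Span(100, 103), Span(0, 3), "ca_only")

    def test_matches_bruteforce_oracle_on_random_coordinates(self, rng):
        def euclid(a, b):
            return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

        for _ in range(50):
            n = int(rng.integers(6, 20))
            residues = []
            for i in range(n):
                atoms = [
                    (name, np.round(rng.uniform(-30, 30, 3), 3))
                    for name in ("N", "CA", "C", "O")[: int(rng.integers(1, 5))]
                ]
                residues.append(ChainResidue(i + 1, "ALA", "A", atoms))
            chain = StructureChain("A", residues, mapping={i: i for i in range(n)})
            sa = Span(0, int(rng.integers(1, n // 2)))
            sb = Span(int(rng.integers(n // 2, n - 1)), n)
            got = min_span_distance(chain, sa, sb, "all_heavy")
            expect = min(
                euclid(ca, cb)
                for i in range(sa.start, sa.end)
                for _, ca in residues[i].atoms
                for j in range(sb.start, sb.end)
                for _, cb in residues[j].atoms
            )
            assert got == pytest.approx(expect, abs=1e-9)
            # symmetry, and CA-only is a minimum over a subset
            assert min_span_distance(chain, sb, sa, "all_heavy") == got
            try:
                d_ca = min_span_distance(chain, sa, sb, "ca_only")
                assert d_ca >= got - 1e-12
            except CoverageError:
                pass  # no CA atom fell inside a span


class TestStructuralProximityFlag:
    def test_flag_threshold_arithmetic(self, straight):
        seq, chain = straight
        # LIR WEEL at 1-5, triacidic DEE at 10-13: nearest CAs 4 and 10
        flag10, d, pair = structural_proximity_flag(
            chain, seq, "lir", "triacidic", threshold=10.0, atom_mode="ca_only"
        )
        assert d == pytest.approx(3.8 * 6, abs=1e-9)
        assert not flag10
        flag30, _, _ = structural_proximity_flag(
            chain, seq, "lir", "triacidic", threshold=30.0, atom_mode="ca_only"
        )
        assert flag30

    def test_infinite_threshold_always_flags(self, straight):
        seq, chain = straight
        flag, _, _ = structural_proximity_flag(
            chain, seq, "lir", "triacidic", threshold=math.inf, atom_mode="ca_only"
        )
        assert flag

    def test_missing_class_is_coverage_error(self, straight):
        seq, chain = straight
        with pytest.raises(CoverageError):
            structural_proximity_flag(
                chain, "MAAAAAAAAWEELAAAAAAA", "lir", "triacidic", threshold=10.0
            )
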