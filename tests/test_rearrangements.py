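"""Breakpoint-graph reconstruction, liftover, and interchange formats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromoscope import rearrangements as rx
from chromoscope import simulate as sim


def make_junction(jid, ca, pa, sa, cb, pb, sb):
    return rx.BreakendJunction(jid, ca, pa, sa, cb, pb, sb)


# ---------------------------------------------------------------------------
# BEDPE parsing
# ---------------------------------------------------------------------------


class TestReadJunctions:
    def test_strand_convention(self, tmp_path):
        """'+' keeps the left flank, '-' the right; position is the interval end."""
        p = tmp_path / "j.bedpe"
        p.write_text("chr1\t99\t100\tchr2\t199\t200\tj1\t.\t+\t-\n")
        (j,) = rx.read_junctions(p)
        assert (j.chrom_a, j.pos_a, j.side_a) == ("chr1", 100, "left")
        assert (j.chrom_b, j.pos_b, j.side_b) == ("chr2", 200, "right")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bedpe"
        p.write_text("")
        assert rx.read_junctions(p) == []

    @pytest.mark.parametrize(
        "line,msg",
        [
            ("chr1\t99\t100\tchr2\t199\t200\tj1\t.\n", "malformed"),
            ("chr1\t99\t100\tchr2\t199\t200\tj1\t.\t.\t-\n", "strand"),
            ("chr1\tx\t100\tchr2\t199\t200\tj1\t.\t+\t-\n", "coordinate"),
        ],
    )
    def test_malformed_lines_name_the_line(self, tmp_path, line, msg):
        p = tmp_path / "bad.bedpe"
        p.write_text(line)
        with pytest.raises(ValueError, match=f"1.*{msg}|{msg}"):
            rx.read_junctions(p)

    def test_fig1_preset_roundtrip(self, tmp_path, fig1):
        p = tmp_path / "fig1.bedpe"
        rx.write_junctions_bedpe(fig1.junctions, p)
        back = rx.read_junctions(p)
        assert back == fig1.junctions
        assert len(back) == 17
        assert {j.chrom_a for j in back} | {j.chrom_b for j in back} == {
            "chr1", "chr3", "chr7", "chr12"
        }


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


class TestSegmentReference:
    def test_single_cut(self):
        j = make_junction("j1", "chr1", 100, "left", "chr1", 200, "right")
        segs = rx.segment_reference([j], {"chr1": 300})
        assert [(s.start, s.end) for s in segs] == [(0, 100), (100, 200), (200, 300)]

    def test_unaffected_chromosome_is_one_segment(self):
        j = make_junction("j1", "chr1", 100, "left", "chr1", 200, "right")
        segs = rx.segment_reference([j], {"chr1": 300, "chr2": 50})
        assert [(s.chrom, s.start, s.end) for s in segs if s.chrom == "chr2"] == [
            ("chr2", 0, 50)
        ]

    def test_out_of_range_breakend_names_junction(self):
        j = make_junction("jX", "chr1", 400, "left", "chr1", 200, "right")
        with pytest.raises(rx.RearrangementError, match="jX"):
            rx.segment_reference([j], {"chr1": 300})

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(min_value=1, max_value=999), min_size=0, max_size=20))
    def test_k_cuts_give_k_plus_1_segments(self, cuts):
        """Tiling invariant against a brute-force sort of the cut positions."""
        junctions = [
            make_junction(f"j{i}", "chr1", p, "left", "chr2", 10, "right")
            for i, p in enumerate(sorted(cuts))
        ]
        segs = rx.segment_reference(junctions, {"chr1": 1000, "chr2": 20})
        on1 = [s for s in segs if s.chrom == "chr1"]
        assert len(on1) == len(cuts) + 1
        bounds = [0, *sorted(cuts), 1000]
        assert [(s.start, s.end) for s in on1] == list(zip(bounds[:-1], bounds[1:]))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


class TestAssembleDerivatives:
    def test_identity(self):
        rset = rx.assemble_derivatives([], chrom_lengths={"chr1": 100, "chr2": 200})
        assert [d.parts for d in rset.derivatives] == [
            [("chr1:0-100", "forward")],
            [("chr2:0-200", "forward")],
        ]
        assert rset.deleted == []

    def test_reciprocal_translocation(self):
        """Hand-enumerated 4-node breakpoint graph of a balanced exchange."""
        j1 = make_junction("j1", "chrA", 100, "left", "chrB", 150, "right")
        j2 = make_junction("j2", "chrB", 150, "left", "chrA", 100, "right")
        rset = rx.assemble_derivatives([j1, j2], chrom_lengths={"chrA": 300, "chrB": 400})
        assert [d.parts for d in rset.derivatives] == [
            [("chrA:0-100", "forward"), ("chrB:150-400", "forward")],
            # normalized: the der starting at chrB:0 is reversed so that its
            # first part (chrA:100) sorts before chrB:0
            [("chrA:100-300", "reverse"), ("chrB:0-150", "reverse")],
        ]
        assert rset.deleted == []

    def test_deletion_junction(self):
        j = make_junction("j1", "chr1", 100, "left", "chr1", 200, "right")
        rset = rx.assemble_derivatives([j], chrom_lengths={"chr1": 300})
        assert [d.parts for d in rset.derivatives] == [
            [("chr1:0-100", "forward"), ("chr1:200-300", "forward")]
        ]
        assert [(s.start, s.end) for s in rset.deleted] == [(100, 200)]

    def test_conflicting_junctions_rejected(self):
        j1 = make_junction("j1", "chr1", 100, "left", "chr1", 200, "right")
        j2 = make_junction("j2", "chr1", 100, "left", "chr2", 30, "right")
        with pytest.raises(rx.ConflictingJunctionsError, match="duplications"):
            rx.assemble_derivatives([j1, j2], chrom_lengths={"chr1": 300, "chr2": 50})

    def test_circular_derivative_rejected(self):
        # excise [100, 200) and religate it head-to-tail: a ring without telomeres
        j1 = make_junction("j1", "chr1", 100, "left", "chr1", 200, "right")
        j2 = make_junction("j2", "chr1", 200, "left", "chr1", 100, "right")
        with pytest.raises(rx.CircularDerivativeError):
            rx.assemble_derivatives([j1, j2], chrom_lengths={"chr1": 300})

    def test_fig1_preset_topology(self, fig1):
        rset = rx.assemble_derivatives(
            fig1.junctions, chrom_lengths=fig1.rearrangement.chrom_lengths
        )
        assert len(rset.junctions) == 17
        assert len(rset.derivatives) == 4
        assert len(rset.deleted) == 4
        assert len(rset.chrom_lengths) == 4

    def test_mass_conservation_random_events(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cfg = sim.SimulationConfig(n_breakpoints=int(rng.integers(0, 13)))
            junctions, _ = sim.simulate_chromothripsis(cfg, rng)
            rset = rx.assemble_derivatives(junctions, chrom_lengths=cfg.chrom_lengths)
            total = sum(rset.derivative_lengths().values()) + rset.deleted_length()
            assert total == sum(cfg.chrom_lengths.values())

    def test_determinism(self, fig1):
        a = rx.assemble_derivatives(fig1.junctions, chrom_lengths=FIG1_LENS(fig1))
        b = rx.assemble_derivatives(fig1.junctions, chrom_lengths=FIG1_LENS(fig1))
        assert [(d.name, d.parts) for d in a.derivatives] == [
            (d.name, d.parts) for d in b.derivatives
        ]


def FIG1_LENS(fig1):
    return fig1.rearrangement.chrom_lengths


# ---------------------------------------------------------------------------
# coordinate map and liftover
# ---------------------------------------------------------------------------


class TestCoordinateMap:
    def test_identity_map(self):
        rset = rx.assemble_derivatives([], chrom_lengths={"chr1": 50})
        cmap = rx.build_coordinate_map(rset)
        res = rx.liftover(cmap, "chr1", 5, "ref2der")
        assert (res.name, res.pos, res.orientation) == ("der1_chr1", 5, "forward")

    def test_reflection_arithmetic(self):
        """Derivative [A 0-100 forward, B 0-50 reverse]: position 120 -> B:29."""
        segs = [rx.GenomeSegment("A", 0, 100), rx.GenomeSegment("B", 0, 50)]
        rset = rx.RearrangementSet(
            junctions=[],
            segments=segs,
            derivatives=[
                rx.DerivativeChromosome(
                    "der1_A", [("A:0-100", "forward"), ("B:0-50", "reverse")], "A"
                )
            ],
            deleted=[],
            chrom_lengths={"A": 100, "B": 50},
        )
        cmap = rx.build_coordinate_map(rset)
        res = rx.liftover(cmap, "der1_A", 120, "der2ref")
        assert (res.name, res.pos, res.orientation) == ("B", 29, "reverse")

    def test_deleted_position_is_marked_not_raised(self):
        j = make_junction("j1", "chr1", 100, "left", "chr1", 200, "right")
        rset = rx.assemble_derivatives([j], chrom_lengths={"chr1": 300})
        cmap = rx.build_coordinate_map(rset)
        res = rx.liftover(cmap, "chr1", 150, "ref2der")
        assert res.deleted and res.name is None

    def test_out_of_range_raises(self):
        rset = rx.assemble_derivatives([], chrom_lengths={"chr1": 50})
        cmap = rx.build_coordinate_map(rset)
        with pytest.raises(ValueError):
            rx.liftover(cmap, "chr1", 50, "ref2der")

    def test_every_retained_base_has_unique_image(self):
        """Exhaustive scan on a small genome: the map is a bijection."""
        rng = np.random.default_rng(1)
        cfg = sim.SimulationConfig(
            chrom_lengths={"c1": 5_000, "c2": 4_000}, n_breakpoints=8,
            n_chromosomes_affected=2,
        )
        junctions, _ = sim.simulate_chromothripsis(cfg, rng)
        rset = rx.assemble_derivatives(junctions, chrom_lengths=cfg.chrom_lengths)
        cmap = rx.build_coordinate_map(rset)
        images = set()
        n_deleted = 0
        for chrom, length in cfg.chrom_lengths.items():
            idx, dpos, _rev, deleted = cmap.ref_to_der_many(chrom, np.arange(length))
            n_deleted += int(deleted.sum())
            images |= {(i, p) for i, p, d in zip(idx, dpos, deleted) if not d}
        assert len(images) == sum(cfg.chrom_lengths.values()) - n_deleted
        assert sum(cmap.der_lengths.values()) == len(images)

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(2)
        cfg = sim.SimulationConfig(n_breakpoints=10)
        junctions, _ = sim.simulate_chromothripsis(cfg, rng)
        rset = rx.assemble_derivatives(junctions, chrom_lengths=cfg.chrom_lengths)
        cmap = rx.build_coordinate_map(rset)
        for chrom, length in cfg.chrom_lengths.items():
            pos = rng.integers(0, length, size=2_000)
            idx, dpos, _rev, deleted = cmap.ref_to_der_many(chrom, pos)
            for name in set(cmap.derivative_names[i] for i in idx[~deleted]):
                sel = ~deleted & (idx == cmap.derivative_names.index(name))
                cidx, rpos, _ = cmap.der_to_ref_many(name, dpos[sel])
                assert all(cmap.chrom_names[c] == chrom for c in cidx)
                np.testing.assert_array_equal(rpos, pos[sel])


# ---------------------------------------------------------------------------
# AGP interchange
# ---------------------------------------------------------------------------


class TestAgp:
    def test_identity_one_w_line_per_chromosome(self, tmp_path):
        rset = rx.assemble_derivatives([], chrom_lengths={"chr1": 100, "chr2": 60})
        p = tmp_path / "x.agp"
        rx.write_agp(rset, p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 2 and all("\tW\t" in l for l in lines)

    def test_inversion_gets_minus_orientation(self, tmp_path):
        j1 = make_junction("j1", "chr1", 100, "left", "chr1", 200, "left")
        j2 = make_junction("j2", "chr1", 100, "right", "chr1", 200, "right")
        rset = rx.assemble_derivatives([j1, j2], chrom_lengths={"chr1": 300})
        p = tmp_path / "inv.agp"
        rx.write_agp(rset, p)
        rows = [l.split("\t") for l in p.read_text().splitlines() if not l.startswith("#")]
        assert [r[8] for r in rows] == ["+", "-", "+"]

    def test_write_read_write_byte_identical(self, tmp_path, fig1):
        p1, p2 = tmp_path / "a.agp", tmp_path / "b.agp"
        rx.write_agp(fig1.rearrangement, p1)
        back = rx.read_agp(p1, fig1.rearrangement.chrom_lengths)
        rx.write_agp(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [(d.name, d.parts) for d in back.derivatives] == [
            (d.name, d.parts) for d in fig1.rearrangement.derivatives
        ]
        assert [(s.chrom, s.start, s.end) for s in back.deleted] == [
            (s.chrom, s.start, s.end) for s in fig1.rearrangement.deleted
        ]
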