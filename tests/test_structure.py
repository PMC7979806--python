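"""PDB reading, position mapping, distances, clustering and domain annotation."""

import numpy as np
import pytest

from pikkmap.structure import (
    Atom,
    DomainMap,
    PDBFormatError,
    Residue,
    StructureModel,
    annotate_domain,
    cluster_residues,
    default_domain_map,
    map_position,
    read_domain_map,
    read_pdb,
    residue_distance,
)
from pikkmap.synthetic import ToyStructureSpec, simulate_structure

from oracles import brute_force_clusters


def atom_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" ", element="C"):
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


def ca_only_model(coords, chain="A"):
    residues = [
        Residue(chain, i + 1, "", "ALA", [Atom("CA", "C", *xyz)])
        for i, xyz in enumerate(coords)
    ]
    return StructureModel(chains=[chain], residues={chain: residues})


class TestReadPDB:
    def test_three_atom_fixture_exact_coordinates(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(
            atom_line(1, "N", "GLY", "A", 1, 1.5, 2.25, -3.125, element="N")
            + atom_line(2, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(3, "C", "GLY", "A", 1, 1.0, 1.0, 1.0)
            + "END\n"
        )
        model = read_pdb(path)
        res = model.residue("A", 1)
        assert [a.name for a in res.atoms] == ["N", "CA", "C"]
        assert res.atoms[0].coord.tolist() == [1.5, 2.25, -3.125]

    def test_numbering_gap_becomes_unresolved_range(self, tmp_path):
        path = tmp_path / "gap.pdb"
        lines = [
            atom_line(i, "CA", "ALA", "A", n, float(n), 0.0, 0.0)
            for i, n in enumerate([1, 2, 3, 4, 5, 10, 11, 12], start=1)
        ]
        path.write_text("".join(lines) + "END\n")
        model = read_pdb(path)
        assert model.unresolved["A"] == [(6, 9)]
        assert model.is_unresolved("A", 7)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(
            atom_line(1, "CA", "SER", "A", 1, 0.0, 0.0, 0.0, occ=0.4, altloc="A")
            + atom_line(2, "CA", "SER", "A", 1, 9.0, 0.0, 0.0, occ=0.6, altloc="B")
            + "END\n"
        )
        model = read_pdb(path)
        res = model.residue("A", 1)
        assert len(res.atoms) == 1
        assert res.atoms[0].x == 9.0

    def test_hetatm_and_water_dropped(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(2, "O", "HOH", "A", 101, 5.0, 5.0, 5.0, element="O").replace(
                "ATOM  ", "HETATM"
            )
            + "END\n"
        )
        model = read_pdb(path)
        assert [r.name for r in model.all_residues()] == ["ALA"]

    def test_no_atom_records_errors(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(PDBFormatError, match="no ATOM"):
            read_pdb(path)

    def test_malformed_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        good = atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
        bad = good[:30] + "  xx.xxx" + good[38:]
        path.write_text(good + bad + "END\n")
        with pytest.raises(PDBFormatError, match="line 2"):
            read_pdb(path)

    def test_toy_structure_round_trip(self, tmp_path):
        sim = simulate_structure(ToyStructureSpec(arrangement="helix", n_residues=12))
        sim.write_pdb(tmp_path / "helix.pdb")
        model = read_pdb(tmp_path / "helix.pdb")
        got = np.array([r.atoms[0].coord for r in model.all_residues()])
        assert np.allclose(got, sim.coords, atol=1e-3)


class TestMapPosition:
    @pytest.fixture
    def gapped_model(self, tmp_path):
        lines = [
            atom_line(i, "CA", "ALA", "A", n, float(n), 0.0, 0.0)
            for i, n in enumerate([1, 2, 3, 4, 5, 10, 11, 12], start=1)
        ]
        path = tmp_path / "gap.pdb"
        path.write_text("".join(lines) + "END\n")
        return read_pdb(path)

    def test_resolved_position(self, gapped_model):
        res = map_position(gapped_model, "A", 3)
        assert res is not None and res.number == 3

    def test_gap_position_reported_unresolved(self, gapped_model):
        assert map_position(gapped_model, "A", 7) is None

    def test_offset_shifts_lookup(self, gapped_model):
        # protein position 15 with offset -5 lands on author residue 10
        res = map_position(gapped_model, "A", 15, offset=-5)
        assert res is not None and res.number == 10

    def test_outside_span_errors(self, gapped_model):
        with pytest.raises(IndexError):
            map_position(gapped_model, "A", 99)


class TestResidueDistance:
    def test_three_four_five_triangle(self):
        model = ca_only_model([(0, 0, 0), (3, 4, 0)])
        assert residue_distance(model, ("A", 1), ("A", 2), "ca") == pytest.approx(5.0)

    def test_self_distance_zero_min_heavy(self):
        model = ca_only_model([(1, 2, 3)])
        assert residue_distance(model, ("A", 1), ("A", 1), "min_heavy") == 0.0

    def test_unresolved_residue_errors(self):
        model = ca_only_model([(0, 0, 0), (3, 4, 0)])
        model.unresolved["A"] = [(3, 5)]
        with pytest.raises(ValueError, match="unresolved"):
            residue_distance(model, ("A", 1), ("A", 4))

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-20, 20, size=(6, 3))
        model = ca_only_model(coords)
        for _ in range(10):
            i, j, k = rng.choice(6, size=3, replace=False) + 1
            dij = residue_distance(model, ("A", int(i)), ("A", int(j)))
            dji = residue_distance(model, ("A", int(j)), ("A", int(i)))
            dik = residue_distance(model, ("A", int(i)), ("A", int(k)))
            dkj = residue_distance(model, ("A", int(k)), ("A", int(j)))
            assert dij == dji
            assert dij <= dik + dkj + 1e-9


class TestClusterResidues:
    def test_single_residue_is_singleton(self):
        model = ca_only_model([(0, 0, 0)])
        assert cluster_residues(model, [("A", 1)], cutoff=24.0) == [[("A", 1)]]

    def test_all_pairs_beyond_cutoff(self):
        model = ca_only_model([(0, 0, 0), (50, 0, 0), (0, 50, 0)])
        clusters = cluster_residues(model, [("A", i) for i in (1, 2, 3)], cutoff=24.0)
        assert sorted(len(c) for c in clusters) == [1, 1, 1]

    def test_empty_residue_list(self):
        model = ca_only_model([(0, 0, 0)])
        assert cluster_residues(model, [], cutoff=10.0) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_threshold_graph_components_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        coords = rng.uniform(0, 30, size=(n, 3))
        cutoff = float(rng.uniform(5, 20))
        model = ca_only_model(coords)
        clusters = cluster_residues(model, [("A", i + 1) for i in range(n)], cutoff)
        got = {frozenset(num - 1 for _, num in c) for c in clusters}
        assert got == brute_force_clusters(coords, cutoff)


class TestDomainMap:
    DMAP = DomainMap([("FAT", 1900, 2656), ("TRD3", 2195, 2475), ("kinase", 2657, 3056)])

    def test_innermost_interval_wins(self):
        assert annotate_domain(self.DMAP, 2300) == "TRD3"
        assert annotate_domain(self.DMAP, 2000) == "FAT"

    def test_boundary_positions_inclusive(self):
        assert annotate_domain(self.DMAP, 2195) == "TRD3"
        assert annotate_domain(self.DMAP, 2475) == "TRD3"
        assert annotate_domain(DomainMap([("spiral", 1, 100)]), 1) == "spiral"

    def test_position_beyond_intervals_unannotated(self):
        assert annotate_domain(self.DMAP, 3057) == "unannotated"

    def test_bundled_atm_map_has_published_boundaries(self):
        dmap = default_domain_map("ATM")
        assert dmap.interval("TRD3") == (2195, 2475)
        assert dmap.length("kinase") == 400

    def test_read_domain_map_tsv(self, tmp_path):
        path = tmp_path / "dm.tsv"
        path.write_text("name\tstart\tend\nkinase\t2245\t2644\n")
        assert read_domain_map(path).interval("kinase") == (2245, 2644)

    def test_bad_interval_errors(self):
        with pytest.raises(ValueError):
            DomainMap([("x", 10, 5)])
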