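"""Structure reading/writing and the three bond-inference strategies."""
import textwrap

import numpy as np
import pytest

from cgweaver.fixtures import FixtureSpec, make_structure
from cgweaver.ledger import WarningLedger
from cgweaver.structure_io import (
    StructureError,
    infer_bonds,
    read_gro,
    read_pdb,
    to_system,
    write_gro,
    write_pdb,
)

MINIMAL_PDB = textwrap.dedent(
    """\
    ATOM      1  N   ALA A   1       0.000   0.500   0.000  1.00  0.00           N
    ATOM      2  CA  ALA A   1       1.200  -0.500   0.000  1.00  0.00           C
    ATOM      3  C   ALA A   1       2.600   0.000   0.000  1.00  0.00           C
    END
    """
)


class TestReadPdb:
    def test_three_atom_minimal_file(self):
        record = read_pdb(MINIMAL_PDB)
        assert len(record.particles) == 3
        assert record.conect_pairs == set()
        # Angstrom -> nm
        np.testing.assert_allclose(record.particles[1].position, [0.12, -0.05, 0.0])

    def test_conect_records_are_symmetrized(self):
        text = MINIMAL_PDB.replace("END", "CONECT    1    2\nCONECT    2    1\nEND")
        record = read_pdb(text)
        assert record.conect_pairs == {(1, 2)}

    def test_altloc_keeps_highest_occupancy(self):
        text = textwrap.dedent(
            """\
            ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
            ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C
            END
            """
        )
        record = read_pdb(text)
        assert len(record.particles) == 1
        assert record.particles[0].altloc == "A"

    def test_altloc_tie_prefers_alphabetical(self):
        text = textwrap.dedent(
            """\
            ATOM      1  CA BALA A   1       9.000   0.000   0.000  0.50  0.00           C
            ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C
            END
            """
        )
        assert read_pdb(text).particles[0].altloc == "A"

    def test_unparseable_coordinate_reports_line(self):
        bad = MINIMAL_PDB.replace("   1.200", "   x.200")
        with pytest.raises(StructureError, match="line 2"):
            read_pdb(bad)

    def test_zero_atoms_is_an_error(self):
        with pytest.raises(StructureError, match="no atoms"):
            read_pdb("TITLE empty\nEND\n")

    def test_first_model_only(self):
        text = "MODEL 1\n" + MINIMAL_PDB.replace("END", "ENDMDL\nMODEL 2\n") + MINIMAL_PDB
        assert len(read_pdb(text).particles) == 3

    def test_parse_agrees_with_biotite(self, tmp_path):
        """Independent oracle: biotite reads the same names and coordinates."""
        pdb = pytest.importorskip("biotite.structure.io.pdb")
        record, _ = make_structure(FixtureSpec("linear_peptide", n_residues=4))
        path = tmp_path / "pep.pdb"
        write_pdb(to_system(record, []), path)
        theirs = pdb.PDBFile.read(str(path)).get_structure(model=1)
        ours = read_pdb(path.read_text())
        assert len(theirs) == len(ours.particles)
        np.testing.assert_allclose(
            np.array([p.position for p in ours.particles]) * 10.0,
            theirs.coord,
            atol=1e-3,
        )
        assert [p.atom_name for p in ours.particles] == list(theirs.atom_name)
        assert [p.resid for p in ours.particles] == list(theirs.res_id)


class TestInferBonds:
    def _two_carbons(self, d_nm):
        text = (
            f"ATOM      1  C1  UNK A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            f"ATOM      2  C2  UNK A   1       {d_nm * 10:.3f}   0.000   0.000  1.00  0.00           C\n"
        )
        return read_pdb(text)

    def test_carbons_at_bonding_distance(self):
        # 0.15 <= 1.2 * (0.076 + 0.076)
        assert infer_bonds(self._two_carbons(0.15), "distance") == [(0, 1)]

    def test_carbons_too_far_apart(self):
        # 0.30 > 0.182
        assert infer_bonds(self._two_carbons(0.30), "distance") == []

    def test_conect_strategy_returns_exactly_those_edges(self):
        record = read_pdb(
            MINIMAL_PDB.replace("END", "CONECT    1    2\nCONECT    2    3\nEND")
        )
        assert infer_bonds(record, "conect") == [(0, 1), (1, 2)]

    def test_distance_needs_positions(self):
        record = self._two_carbons(0.15)
        record.particles[0].position = None
        with pytest.raises(StructureError, match="C1"):
            infer_bonds(record, "distance")

    def test_names_strategy_warns_on_unknown_residue(self, aa_ff):
        record = read_pdb(MINIMAL_PDB.replace("ALA", "XXX"))
        ledger = WarningLedger()
        assert infer_bonds(record, "names", forcefield=aa_ff, ledger=ledger) == []
        assert ledger.entries[0].category == "unrecognized-residue"

    def test_names_and_distance_agree_on_fixture_peptides(self, aa_ff):
        for seq in (None, ["ALA", "HIS", "GLY", "TYR"]):
            record, _ = make_structure(
                FixtureSpec("linear_peptide", n_residues=6, sequence=seq)
            )
            by_names = infer_bonds(record, "names", forcefield=aa_ff)
            by_distance = infer_bonds(record, "distance")
            assert set(by_names) == set(by_distance)

    def test_distance_inference_is_input_order_independent(self):
        record, _ = make_structure(FixtureSpec("linear_peptide", n_residues=5))
        base = set(infer_bonds(record, "distance"))
        reordered, _ = make_structure(FixtureSpec("linear_peptide", n_residues=5))
        reordered.particles = list(reversed(reordered.particles))
        n = len(record.particles)
        remap = {i: n - 1 - i for i in range(n)}
        flipped = {tuple(sorted((remap[a], remap[b]))) for a, b in base}
        assert set(infer_bonds(reordered, "distance")) == flipped

    def test_hydrogens_capped_at_one_bond(self):
        record, _ = make_structure(
            FixtureSpec("linear_peptide", sequence=["ALA", "HIS", "GLY"])
        )
        h_indices = [i for i, p in enumerate(record.particles) if p.element == "H"]
        edges = infer_bonds(record, "distance")
        for h in h_indices:
            assert sum(1 for e in edges if h in e) == 1


class TestToSystem:
    def test_disulfide_bridge_merges_chains(self, disulfide_record):
        record, manifest = disulfide_record
        edges = infer_bonds(record, "distance")
        system = to_system(record, edges)
        assert len(system) == manifest["expected_molecules"] == 1

    def test_without_bridge_two_molecules(self, disulfide_record):
        record, _ = disulfide_record
        s2i = record.serial_to_index()
        sg = {
            i for i, p in enumerate(record.particles) if p.atom_name == "SG"
        }
        edges = [
            e for e in infer_bonds(record, "distance") if not set(e) <= sg
        ]
        assert len(to_system(record, edges)) == 2

    def test_unbonded_cofactor_is_separate_molecule(self, peptide_record):
        record, _ = peptide_record
        from cgweaver.structure_io import Particle

        record.particles.append(
            Particle(
                serial=max(p.serial for p in record.particles) + 1,
                atom_name="MG", resname="MG", resid=99, chain="A",
                element="MG", position=np.array([5.0, 5.0, 5.0]), hetero=True,
            )
        )
        system = to_system(record, infer_bonds(record, "distance"))
        assert len(system) == 2

    def test_particle_count_conserved(self, peptide_record):
        record, _ = peptide_record
        system = to_system(record, infer_bonds(record, "distance"))
        assert system.n_particles == len(record.particles)


class TestWriters:
    def test_gro_round_trip_positions_within_format_precision(self, tmp_path):
        record, _ = make_structure(FixtureSpec("linear_peptide", n_residues=4))
        system = to_system(record, infer_bonds(record, "distance"))
        path = tmp_path / "out.gro"
        write_gro(system, path)
        again = read_gro(path.read_text())
        ours = np.array([p.position for p in record.particles])
        theirs = np.array([p.position for p in again.particles])
        np.testing.assert_allclose(ours, theirs, atol=5e-4)

    def test_cg_gro_has_atom_lines_and_box(self, tmp_path):
        from cgweaver import PipelineConfig, run_pipeline

        record, _ = make_structure(FixtureSpec("linear_peptide", n_residues=4))
        result = run_pipeline(PipelineConfig(structure_record=record))
        path = tmp_path / "cg.gro"
        write_gro(result.system, path)
        lines = path.read_text().splitlines()
        n = int(lines[1])
        assert n == len(result.system.molecules[0])
        assert len(lines) == n + 3  # title, count, atoms, box

    def test_missing_position_written_as_sentinel_with_warning(self, tmp_path):
        record, _ = make_structure(FixtureSpec("linear_peptide", n_residues=3))
        system = to_system(record, infer_bonds(record, "distance"))
        node = next(iter(system.molecules[0].nodes))
        system.molecules[0].nodes[node]["position"] = None
        ledger = WarningLedger()
        path = tmp_path / "out.gro"
        with pytest.raises(StructureError):
            write_gro(system, path)
        write_gro(system, path, allow_missing=True, ledger=ledger)
        assert len(ledger) == 1
        assert ledger.entries[0].category == "missing-coordinates"
        assert "0.000   0.000   0.000" in path.read_text()[: 40 + 45]

    def test_pdb_round_trip(self, tmp_path):
        record, _ = make_structure(FixtureSpec("two_chain_disulfide"))
        system = to_system(record, infer_bonds(record, "distance"))
        path = tmp_path / "out.pdb"
        write_pdb(system, path)
        again = read_pdb(path.read_text())
        assert len(again.particles) == len(record.particles)
        orig = sorted(
            (p.chain, p.resid, p.atom_name) for p in record.particles
        )
        back = sorted((p.chain, p.resid, p.atom_name) for p in again.particles)
        assert orig == back
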