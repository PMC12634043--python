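"""Force-field fragment parsing, serialization round-trips, validation."""
import textwrap

import pytest

from cgweaver.ffdata import (
    FFParseError,
    load_forcefield,
    parse_fragment_file,
    parse_mapping_file,
    parse_rtp,
    serialize_fragments,
    serialize_mappings,
    validate_forcefield,
)
from cgweaver.ledger import WarningLedger

MINIMAL_BLOCK = textwrap.dedent(
    """
    [ block ]
    name XY
    [ atoms ]
    A1 C CT1 0.0
    A2 O OT1 -0.3
    [ bonds ]
    A1 A2 1 0.15 5000
    """
)

LINK_WITH_OFFSETS = textwrap.dedent(
    """
    [ link ]
    [ patterns ]
    BB resname=ALA|GLY
    +BB
    [ edges ]
    BB +BB
    [ angles ]
    -BB BB +BB 2 127 20
    """
)

MODIFICATION = textwrap.dedent(
    """
    [ modification ]
    name HIS-HP
    resname HIS
    [ atoms ]
    ND1 N anchor
    HD1 H added
    [ edges ]
    ND1 HD1
    [ cg ]
    SC2 charge 1.0
    """
)


class TestFragmentParser:
    def test_minimal_block_two_atoms_one_bond(self):
        parsed = parse_fragment_file(MINIMAL_BLOCK)
        blk = parsed.blocks["XY"]
        assert sorted(blk.graph.nodes) == ["A1", "A2"]
        assert len(blk.graph.interactions["bond"]) == 1
        assert blk.graph.interactions["bond"][0].parameters == ("1", "0.15", "5000")

    def test_link_offsets_and_added_angle(self):
        parsed = parse_fragment_file(LINK_WITH_OFFSETS)
        (link,) = parsed.links
        offsets = link.offsets()
        assert offsets == {-1, 0, 1}
        assert len(link.add_interactions) == 1
        assert link.add_interactions[0].kind == "angle"
        assert link.pattern.nodes["BB"]["matchers"]["resname"] == ("ALA", "GLY")

    def test_modification_added_hydrogen_with_anchor(self):
        parsed = parse_fragment_file(MODIFICATION)
        mod = parsed.modifications["HIS-HP"]
        assert mod.added_nodes == ["HD1"]
        assert mod.anchor_nodes == ["ND1"]
        assert mod.bead_edits == [("SC2", "charge", 1.0)]

    def test_duplicate_block_name_is_an_error(self):
        with pytest.raises(FFParseError, match="duplicate"):
            parse_fragment_file(MINIMAL_BLOCK + MINIMAL_BLOCK)

    def test_interaction_on_undeclared_atom_names_atom_and_block(self):
        bad = MINIMAL_BLOCK.replace("A1 A2 1", "A1 A9 1")
        with pytest.raises(FFParseError, match="A9.*XY"):
            parse_fragment_file(bad)

    def test_unknown_directive_warns_and_skips(self):
        ledger = WarningLedger()
        text = MINIMAL_BLOCK + "\n[ quantum ]\nnonsense 1 2\n"
        parsed = parse_fragment_file(text, ledger)
        assert "XY" in parsed.blocks
        assert len(ledger) == 1 and "quantum" in ledger.entries[0].message

    def test_syntax_error_carries_line_number(self):
        text = "[ block ]\nname B\n[ atoms ]\nA1 C\n"
        with pytest.raises(FFParseError, match="line 4"):
            parse_fragment_file(text)

    def test_crlf_and_trailing_whitespace_tolerated(self):
        text = MINIMAL_BLOCK.replace("\n", "  \r\n")
        assert "XY" in parse_fragment_file(text).blocks


class TestMappingParser:
    def test_all_atoms_to_one_bead(self):
        text = "[ mapping ]\nname M\nfrom RES\nto RES\n[ atoms ]\n" + "".join(
            f"1 A{i} B1\n" for i in range(4)
        )
        (m,) = parse_mapping_file(text)
        assert all(m.weights[(1, f"A{i}")] == {(1, "B1"): 1.0} for i in range(4))

    def test_shared_atom_splits_weight_equally(self):
        text = "[ mapping ]\nname M\nfrom RES\nto RES\n[ atoms ]\n1 A B1 B2\n"
        (m,) = parse_mapping_file(text)
        assert m.weights[(1, "A")] == {(1, "B1"): 0.5, (1, "B2"): 0.5}

    def test_two_residue_scope_mapping(self):
        text = textwrap.dedent(
            """
            [ mapping ]
            name PEO2
            from PEO PEO
            to PEO PEO
            [ atoms ]
            1 C1 B1
            1 C2 B1
            1 O1 B1 2:B1
            2 C1 2:B1
            2 C2 2:B1
            2 O1 2:B1
            """
        )
        (m,) = parse_mapping_file(text)
        assert m.resname_scope == ("PEO", "PEO")
        assert m.weights[(1, "O1")] == {(1, "B1"): 0.5, (2, "B1"): 0.5}

    def test_residue_index_outside_scope_is_an_error(self):
        text = "[ mapping ]\nname M\nfrom RES\nto RES\n[ atoms ]\n2 A B1\n"
        with pytest.raises(FFParseError, match="outside scope"):
            parse_mapping_file(text)


RTP = textwrap.dedent(
    """
    [ bondedtypes ]
    1 5 9 2
    [ ALA ]
     [ atoms ]
       N   NH1  -0.47  0
       CA  CT1   0.07  1
       CB  CT3  -0.27  1
       C   C     0.51  2
       O   O    -0.51  2
     [ bonds ]
       CB CA
       N  CA
       C  CA
       O  C
       -C N
     [ impropers ]
    """
)


class TestRtpParser:
    def test_minimal_residue_entry(self):
        data = parse_rtp(RTP)
        blk = data.blocks["ALA"]
        assert sorted(blk.graph.nodes) == ["C", "CA", "CB", "N", "O"]
        assert len(blk.graph.interactions["bond"]) == 4  # intra-residue only

    def test_prev_residue_bond_becomes_link_with_offsets(self):
        data = parse_rtp(RTP)
        (link,) = data.links
        assert link.offsets() == {-1, 0}
        assert link.add_interactions[0].kind == "bond"

    def test_empty_impropers_section_gives_no_impropers(self):
        data = parse_rtp(RTP)
        assert "improper" not in data.blocks["ALA"].graph.interactions

    def test_residue_without_atoms_is_an_error(self):
        with pytest.raises(FFParseError, match="no \\[atoms\\]"):
            parse_rtp("[ GLY ]\n[ impropers ]\n[ ALA ]\n[ atoms ]\nN NH1 0 0\n")

    def test_rtp_block_isomorphic_to_hand_converted_fragment_block(self):
        data = parse_rtp(RTP)
        fragment = textwrap.dedent(
            """
            [ block ]
            name ALA
            nrexcl 3
            [ atoms ]
            N  N NH1 -0.47
            CA C CT1 0.07
            CB C CT3 -0.27
            C  C C 0.51
            O  O O -0.51
            [ bonds ]
            CB CA
            N CA
            C CA
            O C
            """
        )
        other = parse_fragment_file(fragment).blocks["ALA"]
        a, b = data.blocks["ALA"].graph, other.graph
        assert set(a.nodes) == set(b.nodes)
        assert {tuple(sorted(e)) for e in a.edges} == {tuple(sorted(e)) for e in b.edges}


class TestRoundTrips:
    def test_fragment_dialect_round_trip_is_identity(self, aa_ff):
        text = serialize_fragments(
            aa_ff.blocks.values(), aa_ff.links, aa_ff.modifications.values()
        )
        again = parse_fragment_file(text)
        assert set(again.blocks) == set(aa_ff.blocks)
        for name in aa_ff.blocks:
            assert again.blocks[name] == aa_ff.blocks[name]
        assert again.links == aa_ff.links
        for name in aa_ff.modifications:
            assert again.modifications[name] == aa_ff.modifications[name]

    def test_cg_fragment_round_trip_is_identity(self, cg_ff):
        text = serialize_fragments(
            cg_ff.blocks.values(), cg_ff.links, cg_ff.modifications.values()
        )
        again = parse_fragment_file(text)
        for name in cg_ff.blocks:
            assert again.blocks[name] == cg_ff.blocks[name]
        assert again.links == cg_ff.links

    def test_mapping_round_trip_is_identity(self, cg_mappings):
        text = serialize_mappings(cg_mappings)
        again = parse_mapping_file(text)
        assert again == cg_mappings


class TestValidateAndBundled:
    def test_bundled_demo_data_is_consistent(self, cg_ff, cg_mappings):
        assert validate_forcefield(cg_ff, cg_mappings) == []

    def test_mapping_to_unknown_block_is_diagnosed(self, cg_ff, cg_mappings):
        bad = parse_mapping_file(
            "[ mapping ]\nname X\nfrom XYZ\nto XYZ\n[ atoms ]\n1 A B1\n"
        )
        diags = validate_forcefield(cg_ff, list(cg_mappings) + bad)
        assert any("unknown block 'XYZ'" in d for d in diags)

    def test_link_matching_no_block_is_diagnosed(self, cg_ff, cg_mappings):
        extra = parse_fragment_file(
            "[ link ]\n[ patterns ]\nBB resname=NOPE\n=BB resname=NOPE\n"
            "[ edges ]\nBB =BB\n[ bonds ]\nBB =BB 1 0.3 100\n"
        )
        import dataclasses
        ff = dataclasses.replace(cg_ff, links=list(cg_ff.links) + extra.links)
        diags = validate_forcefield(ff, cg_mappings)
        assert any("matches no known block" in d for d in diags)

    def test_beads_aggregate_two_to_five_heavy_atoms(self, cg_mappings, aa_ff):
        """Every demo bead groups 2-5 non-hydrogen source atoms."""
        for mapping in cg_mappings:
            per_bead = {}
            for (residx, atom), targets in mapping.weights.items():
                resname = mapping.from_resnames[residx - 1]
                element = aa_ff.blocks[resname].graph.nodes[atom].get("element", "")
                if element.upper() == "H":
                    continue
                for bead, w in targets.items():
                    if w > 0:
                        per_bead.setdefault(bead, set()).add((residx, atom))
            for bead, atoms in per_bead.items():
                assert 2 <= len(atoms) <= 5, (mapping.name, bead, atoms)

    def test_alias_table_resolves_protonation_names(self, aa_ff):
        assert aa_ff.aliases["HSP"] == ("HIS", ("HIS-HP",))
        assert aa_ff.aliases["HSD"] == ("HISD", ())
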