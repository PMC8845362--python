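import numpy as np
import pytest

from pocketmotion import (
    Atom,
    Ligand,
    Structure,
    build_pair,
    check_resolution,
    classify_oligomer,
    parse_structure,
    write_pdb,
)
from pocketmotion import synthetic as syn
from pocketmotion.structure_io import (
    PairingError,
    StructureError,
    _collapse_altlocs,
    build_residue_map,
    load_additive_list,
    pair_category,
    sequence_identity,
)
from pocketmotion.structures import APO_APO, APO_HOLO, HOLO_HOLO_DIFF, HOLO_HOLO_SAME


def _holo_structure(seed=5, n=40, comp="LIG"):
    pair, _ = syn.make_overall_pair("holo_holo_same", 1.0, seed=seed, n_residues=n)
    s = pair.first
    s.ligands[0].comp_id = comp
    return s


# ---------------------------------------------------------------------- parsing


def test_roundtrip_preserves_residues_atoms_and_coords(tmp_path):
    s = _holo_structure()
    path = tmp_path / "s.pdb"
    write_pdb(s, path)
    s2 = parse_structure(path, additive_list=set())
    assert s2.n_residues == s.n_residues
    for ra, rb in zip(s.residues(), s2.residues()):
        assert (ra.res_name, ra.seq_id, len(ra.atoms)) == (rb.res_name, rb.seq_id, len(rb.atoms))
    c1 = np.vstack([a.coords for r in s.residues() for a in r.atoms])
    c2 = np.vstack([a.coords for r in s2.residues() for a in r.atoms])
    assert np.abs(c1 - c2).max() < 1.5e-3  # PDB stores 3 decimals
    assert [l.comp_id for l in s2.ligands] == ["LIG"]
    assert s2.resolution == pytest.approx(1.5, abs=1e-3)


def test_additive_filtering_sets_state_and_is_idempotent(tmp_path):
    s = _holo_structure(comp="PEG")
    # add a "water" and keep PEG as the only hetero group
    path = tmp_path / "s.pdb"
    write_pdb(s, path)
    parsed = parse_structure(path, additive_list={"PEG"})
    assert parsed.state == "apo"
    assert parsed.ligands == []
    # idempotence: writing the filtered structure and re-filtering changes nothing
    path2 = tmp_path / "s2.pdb"
    write_pdb(parsed, path2)
    again = parse_structure(path2, additive_list={"PEG"})
    assert again.state == "apo" and again.n_residues == parsed.n_residues


def test_non_additive_ligand_makes_structure_holo(tmp_path):
    s = _holo_structure(comp="ATP")
    path = tmp_path / "s.pdb"
    write_pdb(s, path)
    parsed = parse_structure(path, additive_list={"PEG"})
    assert parsed.state == "holo"
    assert [l.comp_id for l in parsed.ligands] == ["ATP"]


def test_small_hetero_groups_do_not_define_holo(tmp_path):
    s = _holo_structure(comp="XXX")
    s.ligands[0].atoms = s.ligands[0].atoms[:2]  # 2 heavy atoms: below threshold
    path = tmp_path / "s.pdb"
    write_pdb(s, path)
    parsed = parse_structure(path, additive_list=set())
    assert parsed.state == "apo"


def test_protein_only_file_is_apo(tmp_path):
    s = _holo_structure()
    s.ligands = []
    path = tmp_path / "s.pdb"
    write_pdb(s, path)
    parsed = parse_structure(path)
    assert parsed.state == "apo" and parsed.ligands == []


def test_unreadable_and_empty_files_raise(tmp_path):
    with pytest.raises(StructureError):
        parse_structure(tmp_path / "missing.pdb")
    hetero_only = tmp_path / "het.pdb"
    hetero_only.write_text(
        "HETATM    1  C1  ATP A 900      11.000  22.000  33.000  1.00  0.00           C\n"
        "END\n"
    )
    with pytest.raises(StructureError):
        parse_structure(hetero_only)


def test_altloc_collapse_keeps_highest_occupancy_tie_by_label():
    atoms = [
        Atom("CA", "C", [0, 0, 0], occupancy=0.4, altloc="B"),
        Atom("CA", "C", [1, 0, 0], occupancy=0.6, altloc="A"),
        Atom("CB", "C", [2, 0, 0], occupancy=0.5, altloc="B"),
        Atom("CB", "C", [3, 0, 0], occupancy=0.5, altloc="A"),
    ]
    kept = {a.name: a for a in _collapse_altlocs(atoms)}
    assert kept["CA"].occupancy == 0.6
    assert kept["CB"].altloc == "A"  # tie broken by earlier altloc


def test_additive_list_file_parsing(tmp_path):
    f = tmp_path / "add.txt"
    f.write_text("# comment\nPEG\ngol  # inline\n\nSO4\n")
    codes = load_additive_list(f)
    assert {"PEG", "GOL", "SO4", "HOH"} <= codes


# ---------------------------------------------------------------------- filters


def test_resolution_filter_is_strict():
    s = _holo_structure()
    s.resolution = 2.5
    assert check_resolution(s, 3.0)
    s.resolution = 3.0
    assert not check_resolution(s, 3.0)
    s.resolution = None
    assert not check_resolution(s, 3.0)


def test_oligomer_classification():
    s = _holo_structure(n=40)
    assert classify_oligomer(s) == "monomer"
    # duplicate chain -> homo-multimer
    import copy

    dup = copy.deepcopy(s.chains["A"])
    for r in dup:
        r.chain_id = "B"
    s.chains["B"] = dup
    assert classify_oligomer(s) == "homo-multimer"
    # scramble chain B's sequence -> hetero
    rng = np.random.default_rng(0)
    other = [aa for aa in syn.AA_ORDER]
    for r in s.chains["B"]:
        r.res_name = str(rng.choice(other))
    assert classify_oligomer(s) == "hetero"


def test_sequence_identity_bounds():
    assert sequence_identity("ACDEF", "ACDEF") == 1.0
    assert sequence_identity("AAAA", "CCCC") == 0.0
    assert 0.0 < sequence_identity("ACDEF", "ACDEY") < 1.0


# ---------------------------------------------------------------------- pairing


def test_pair_categories():
    apo1, _ = syn.make_overall_pair("apo_apo", 1.0, seed=1)
    assert apo1.category == APO_APO
    ah, _ = syn.make_overall_pair("apo_holo", 1.0, seed=2)
    assert ah.category == APO_HOLO
    hh_same, _ = syn.make_overall_pair("holo_holo_same", 1.0, seed=3)
    assert hh_same.category == HOLO_HOLO_SAME
    comp = {l.comp_id for l in hh_same.first.ligands} & {
        l.comp_id for l in hh_same.second.ligands
    }
    assert comp
    hh_diff, _ = syn.make_overall_pair("holo_holo_diff", 1.0, seed=4)
    assert hh_diff.category == HOLO_HOLO_DIFF


def test_self_pairing_maps_every_residue():
    s = _holo_structure()
    pair = build_pair(s, s.copy())
    assert len(pair.residue_map) == s.n_residues
    assert pair.category == HOLO_HOLO_SAME


def test_residue_map_is_inverse_of_swapped_map():
    pair, _ = syn.make_pocket_pair("PE", seed=2)
    fwd = {(ra.key, rb.key) for ra, rb in build_residue_map(pair.first, pair.second)}
    rev = {(rb.key, ra.key) for ra, rb in build_residue_map(pair.second, pair.first)}
    assert fwd == rev


def test_too_few_mapped_residues_raises():
    s = _holo_structure(n=40)
    other = _holo_structure(seed=99, n=40)
    other.chains["A"] = other.chains["A"][:20]  # at most 20 residues can map
    with pytest.raises(PairingError):
        build_pair(s, other)


def test_pair_category_function_consistency():
    a = _holo_structure(comp="ATP")
    b = _holo_structure(seed=6, comp="ATP")
    assert pair_category(a, b) == HOLO_HOLO_SAME
    b.ligands[0].comp_id = "GTP"
    assert pair_category(a, b) == HOLO_HOLO_DIFF
    b.ligands = []
    assert pair_category(a, b) == APO_HOLO
    a.ligands = []
    assert pair_category(a, b) == APO_APO
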