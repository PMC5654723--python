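"""PDB reading/writing, active-site location and domain assignment."""

import numpy as np
import pytest

from pdiflex.geomsim import ConformerTrajectory
from pdiflex.structure import (ActiveSiteError, DomainAnnotation, EmptyStructureError,
                               PDBParseError, StructuralMismatchError, assign_domains,
                               locate_active_sites, parse_pdb_text, write_ensemble,
                               write_structure, parse_pdb)

MINIMAL_ATOM = (
    "ATOM      1  CA  ALA A   1      11.104  13.207   2.100  1.00 20.00           C\n"
)


def test_single_atom_file():
    s = parse_pdb_text(MINIMAL_ATOM)
    assert len(s.atoms) == 1
    assert s.chains == ["A"]
    assert s.missing_ranges == []
    np.testing.assert_allclose(s.atoms[0].position, [11.104, 13.207, 2.100])


def test_no_atoms_is_an_error():
    with pytest.raises(EmptyStructureError):
        parse_pdb_text("HEADER    NOTHING\nEND\n")


def test_malformed_record_names_line():
    text = MINIMAL_ATOM + "ATOM      2  CA  ALA A   2      xx.xxx   0.000   0.000\n"
    with pytest.raises(PDBParseError, match="line 2"):
        parse_pdb_text(text)


def test_altloc_highest_occupancy_wins():
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C\n"
    )
    s = parse_pdb_text(text, altloc_policy="highest-occupancy")
    assert s.atoms[0].position[0] == 5.0
    s = parse_pdb_text(text, altloc_policy="first")
    assert s.atoms[0].position[0] == 0.0
    # occupancy tie: altloc letter order breaks it
    tie = text.replace("0.40", "0.50").replace("0.60", "0.50")
    s = parse_pdb_text(tie)
    assert s.atoms[0].position[0] == 0.0


def test_missing_ranges_from_numbering_gap():
    lines = []
    for i, resnum in enumerate([248, 249, 255, 256], start=1):
        lines.append(f"ATOM  {i:>5d}  CA  ALA A{resnum:>4d}    "
                     f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
    s = parse_pdb_text("\n".join(lines))
    assert s.missing_ranges == [("A", 250, 254)]


def test_missing_ranges_from_remark_465():
    lines = ["REMARK 465   M RES C SSSEQI",
             "REMARK 465     ALA A   250",
             "REMARK 465     ALA A   251"]
    for i, resnum in enumerate([249, 252], start=1):
        lines.append(f"ATOM  {i:>5d}  CA  ALA A{resnum:>4d}    "
                     f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
    s = parse_pdb_text("\n".join(lines))
    assert s.missing_ranges == [("A", 250, 251)]


def test_water_dropped_hetatm_policy():
    text = (MINIMAL_ATOM +
            "HETATM    2  O   HOH A 101       1.000   2.000   3.000  1.00  0.00           O\n"
            "HETATM    3  S1  DTT A 102       4.000   5.000   6.000  1.00  0.00           S\n")
    assert len(parse_pdb_text(text).atoms) == 1
    kept = parse_pdb_text(text, keep_hetatm=True)
    assert [a.name for a in kept.atoms] == ["CA", "S1"]


def test_roundtrip_write_parse(tmp_path, dumbbell):
    path = tmp_path / "out.pdb"
    write_structure(dumbbell, path)
    back = parse_pdb(path)
    np.testing.assert_allclose(back.coords, dumbbell.coords, atol=5e-4)
    assert [a.name for a in back.atoms] == [a.name for a in dumbbell.atoms]
    assert [a.residue_number for a in back.atoms] == [a.residue_number
                                                     for a in dumbbell.atoms]


def test_roundtrip_against_gemmi(tmp_path, dumbbell):
    """The writer's output must be readable by an independent PDB library."""
    gemmi = pytest.importorskip("gemmi")
    path = tmp_path / "out.pdb"
    write_structure(dumbbell, path)
    st = gemmi.read_structure(str(path))
    got = np.array([[at.pos.x, at.pos.y, at.pos.z]
                    for model in st for chain in model
                    for res in chain for at in res])
    np.testing.assert_allclose(got[: len(dumbbell.atoms)], dumbbell.coords, atol=5e-4)


def test_ensemble_roundtrip_and_model_count(tmp_path, dumbbell):
    coords = dumbbell.coords
    traj = ConformerTrajectory(dumbbell, 7, {-1: coords - 1.0, 0: coords,
                                             1: coords + 1.0})
    path = tmp_path / "ens.pdb"
    write_ensemble(traj, path)
    text = path.read_text()
    assert text.count("MODEL ") == 3
    # model 1 is the most negative index
    from pdiflex.structure import parse_pdb as pp
    m1 = pp(path, model_policy=1)
    np.testing.assert_allclose(m1.coords, coords - 1.0, atol=5e-4)
    m3 = pp(path, model_policy=3)
    np.testing.assert_allclose(m3.coords, coords + 1.0, atol=5e-4)


def test_empty_ensemble_is_an_error(tmp_path, dumbbell):
    traj = ConformerTrajectory(dumbbell, 7, {})
    with pytest.raises(StructuralMismatchError):
        write_ensemble(traj, tmp_path / "x.pdb")
    assert not (tmp_path / "x.pdb").exists()


def _cghc_structure(positions):
    """Poly-ALA chain with CGHC planted at the given start residues."""
    names = {}
    n_res = max(positions) + 10
    for p in positions:
        for k, nm in enumerate(("CYS", "GLY", "HIS", "CYS")):
            names[p + k] = nm
    lines = []
    for r in range(1, n_res + 1):
        lines.append(f"ATOM  {r:>5d}  CA  {names.get(r, 'ALA'):>3s} A{r:>4d}    "
                     f"{r * 3.8:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
    return parse_pdb_text("\n".join(lines))


@pytest.mark.parametrize("sites", [(5, 40), (2, 17)])
def test_locate_active_sites_finds_planted_motifs(sites):
    s = _cghc_structure(list(sites))
    pair = locate_active_sites(s)
    assert pair.site_a == ("A", sites[0])
    assert pair.site_a_prime == ("A", sites[1])


def _single_motif():
    return _cghc_structure([5])


def test_locate_active_sites_requires_two_motifs():
    with pytest.raises(ActiveSiteError, match="CGHC"):
        locate_active_sites(_single_motif())


def test_locate_active_sites_renumbering_invariance():
    s = _cghc_structure([5, 40])
    shifted_atoms = [a for a in s.atoms]
    from dataclasses import replace
    shifted = type(s)([replace(a, residue_number=a.residue_number + 17)
                       for a in s.atoms], list(s.chains))
    del shifted_atoms
    pair = locate_active_sites(shifted)
    assert pair.site_a == ("A", 22)
    assert pair.site_a_prime == ("A", 57)


HPDI_TABLE = DomainAnnotation(
    [("a", [(1, 117)]), ("b", [(118, 222)]), ("bp", [(223, 328)]),
     ("x", [(329, 348)]), ("ap", [(349, 462)])], "mature", 17)


def test_assign_domains_x_linker_label():
    s = _cghc_structure([36, 380])
    labelled = assign_domains(s, HPDI_TABLE)
    idx = s.atom_index("A", 347, "CA")
    assert labelled.domain_labels[idx] == "x"


def test_assign_domains_empty_table():
    s = _single_motif()
    labelled = assign_domains(s, DomainAnnotation([], "mature", 17))
    assert set(labelled.domain_labels) == {"unassigned"}


def test_assign_domains_offset_conventions_agree():
    s = _cghc_structure([36, 380])
    translation_table = HPDI_TABLE.to_convention("translation-product")
    a = assign_domains(s, HPDI_TABLE).domain_labels
    b = assign_domains(s, translation_table).domain_labels
    assert a == b
    # and the round trip is the identity
    back = translation_table.to_convention("mature")
    assert back.domains == HPDI_TABLE.domains


def test_overlapping_table_rejected():
    with pytest.raises(ValueError, match="overlap"):
        DomainAnnotation([("a", [(1, 100)]), ("b", [(90, 150)])])
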