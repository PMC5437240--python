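import numpy as np
import pytest

from hexbind.io import AtomRecord, Structure
from hexbind.sites import (
    assign_ligand_sites,
    classify_zinc_site,
    detect_contacts,
)
from hexbind.synthetic import _indole_template


def _atom(name, element, resname, chain, resnum, pos, hetero=False):
    return AtomRecord(
        atom_name=name,
        element=element,
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum,
        position=np.asarray(pos, float),
        is_hetero=hetero,
    )


# ---------------------------------------------------------------------------
# zinc coordination


def test_tetrahedral_zinc_with_axial_chloride(zinc_hexamers):
    sites = classify_zinc_site(zinc_hexamers["tetrahedral"])
    assert len(sites) == 1
    z = sites[0]
    assert z.coordination_number == 4
    assert z.geometry == "tetrahedral"
    assert z.axial_species == "CL"
    his = [a for a, _ in z.ligand_atoms if a.residue_name == "HIS"]
    assert len(his) == 3 and all(a.atom_name == "NE2" for a in his)


def test_octahedral_zinc_his_plus_waters(zinc_hexamers):
    sites = classify_zinc_site(zinc_hexamers["octahedral"])
    assert len(sites) == 1
    z = sites[0]
    assert z.coordination_number == 6
    assert z.geometry == "octahedral"
    waters = [a for a, _ in z.ligand_atoms if a.residue_name == "HOH"]
    assert len(waters) == 3


def test_undercoordinated_zinc_is_other():
    atoms = [
        _atom("ZN", "ZN", "ZN", "W", 1, [0, 0, 0], hetero=True),
        _atom("O", "O", "HOH", "W", 2, [2.0, 0, 0], hetero=True),
        _atom("O", "O", "HOH", "W", 3, [0, 2.0, 0], hetero=True),
    ]
    sites = classify_zinc_site(Structure(atoms=atoms))
    assert sites[0].coordination_number == 2
    assert sites[0].geometry == "other"


def test_no_zinc_returns_empty(bare_hexamers):
    assert classify_zinc_site(bare_hexamers["T6"]) == []


def test_zinc_geometry_stable_under_coordinate_jitter(zinc_hexamers):
    """±0.05 Å jitter must not flip the geometry label (100 replicates)."""
    rng = np.random.default_rng(7)
    for label, fixture in zinc_hexamers.items():
        base = fixture.positions()
        for _ in range(50):
            jit = rng.uniform(-0.05, 0.05, base.shape)
            moved = Structure(
                atoms=[
                    _atom(
                        a.atom_name, a.element, a.residue_name, a.chain_id,
                        a.residue_number, p, a.is_hetero,
                    )
                    for a, p in zip(fixture.atoms, base + jit)
                ]
            )
            got = classify_zinc_site(moved)[0].geometry
            assert got == label


# ---------------------------------------------------------------------------
# hydrogen bonds and π-contacts


def test_serotonin_hb_and_pi_anchor_distances(insser_hexamer):
    """The built site I geometry is recovered by contact detection: the
    serotonin OH - Cys A6 carbonyl bond at 2.42 Å and the His B5
    NE2 - pyrrole centroid contact at 3.50 Å."""
    contacts = detect_contacts(insser_hexamer)
    oh_hbs = [
        c
        for c in contacts
        if c.classification == "HB"
        and {c.donor_atom.atom_name, c.acceptor_atom.atom_name} == {"O5", "O"}
        and {c.donor_atom.residue_name, c.acceptor_atom.residue_name}
        == {"SRO", "CYS"}
    ]
    assert len(oh_hbs) == 3  # one per site I serotonin
    for c in oh_hbs:
        assert c.distance == pytest.approx(2.42, abs=0.01)
    pis = [
        c
        for c in contacts
        if c.classification == "pi_contact"
        and c.donor_atom.atom_name == "NE2"
        and c.ring_residue[2] == "SRO"
    ]
    assert len(pis) == 3
    for c in pis:
        assert c.distance == pytest.approx(3.50, abs=0.01)


def test_distant_atoms_make_no_contact():
    atoms = [
        _atom("O", "O", "HOH", "W", 1, [0, 0, 0], hetero=True),
        _atom("N", "N", "GLY", "A", 1, [5.0, 0, 0]),
    ]
    assert detect_contacts(Structure(atoms=atoms)) == []


def test_bonded_and_13_pairs_excluded():
    # N-CA-C-O chain: N..O is a 1-4 pair at short range -> reported;
    # N..C (1-3) and C..O (bonded) are not
    atoms = [
        _atom("N", "N", "GLY", "A", 1, [0, 0, 0]),
        _atom("CA", "C", "GLY", "A", 1, [1.46, 0, 0]),
        _atom("C", "C", "GLY", "A", 1, [2.2, 1.3, 0]),
        _atom("O", "O", "GLY", "A", 1, [1.7, 2.4, 0]),
    ]
    contacts = detect_contacts(Structure(atoms=atoms))
    pairs = {
        frozenset((c.donor_atom.atom_name, c.acceptor_atom.atom_name))
        for c in contacts
    }
    assert frozenset(("N", "O")) in pairs
    assert frozenset(("C", "O")) not in pairs


def test_contacts_monotone_in_cutoff(insser_hexamer):
    def keyset(contacts):
        return {
            (
                c.classification,
                c.donor_atom.chain_id, c.donor_atom.residue_number,
                c.donor_atom.atom_name,
                c.acceptor_atom.chain_id, c.acceptor_atom.residue_number,
                c.acceptor_atom.atom_name,
            )
            for c in contacts
        }

    tight = keyset(detect_contacts(insser_hexamer, hb_cutoff=3.0, pi_cutoff=3.4))
    loose = keyset(detect_contacts(insser_hexamer, hb_cutoff=3.6, pi_cutoff=3.8))
    assert tight <= loose


# ---------------------------------------------------------------------------
# ligand site assignment


def test_insser_fixture_site_assignment(insser_hexamer):
    poses = assign_ligand_sites(insser_hexamer)
    assert len(poses) == 6
    assert sorted(p.site for p in poses) == ["I", "I", "I", "III", "III", "III"]
    for p in poses:
        contacts = {lab for lab, _ in p.contact_residues}
        if p.site == "I":
            assert {"A6", "A11"} <= contacts
        else:
            assert {"A14", "A17"} <= contacts


def test_far_ligand_is_unassigned(insser_hexamer):
    atoms = [a for a in insser_hexamer.atoms if a.residue_name != "SRO"]
    for name, pos in _indole_template().items():
        atoms.append(
            _atom(name, name[0], "SRO", "X", 99, np.asarray(pos) + 200.0,
                  hetero=True)
        )
    poses = assign_ligand_sites(Structure(atoms=atoms))
    assert len(poses) == 1
    assert poses[0].site == "unassigned"
    assert poses[0].contact_residues == []


def test_structure_without_ligands_gives_empty(bare_hexamers):
    assert assign_ligand_sites(bare_hexamers["T6"]) == []
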