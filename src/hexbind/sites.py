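"""Zinc coordination geometry, hydrogen-bond / π-contact detection, and
ligand binding-site assignment on insulin hexamers.

Site assignment follows a contact-fingerprint scheme: each of the three
phenolic sites of the hexamer is described by the canonical residues
that line it (site I — the internal phenolic pocket: Cys A6, Ser A9,
Cys A11, His B5, Leu B17, Glu B21; site II: B9, B12, B16, B17; site III
— the surface pocket between three-fold-related dimers: Leu A13,
Tyr A14, Glu A17, Arg B22).  A ligand is assigned to the site whose
fingerprint residues it contacts in the greatest fraction, provided at
least half of the fingerprint is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import AtomRecord, Structure
from .monomers import identify_monomers

__all__ = [
    "ZincSite",
    "HBond",
    "LigandPose",
    "classify_zinc_site",
    "detect_contacts",
    "assign_ligand_sites",
    "LIGAND_RESNAMES",
    "SITE_FINGERPRINTS",
]

#: Residue-name map for the ligands this pipeline recognises.
LIGAND_RESNAMES = {
    "IPH": "phenol",
    "PHN": "phenol",
    "SRO": "serotonin",
    "5HT": "serotonin",
    "LDP": "dopamine",
    "ARG": "arginine",  # only when flagged as a hetero residue
}

#: Aromatic-ring atom names per residue name, for π-contact detection.
RING_TEMPLATES: dict[str, list[list[str]]] = {
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    ],
    "IPH": [["C1", "C2", "C3", "C4", "C5", "C6"]],
    "PHN": [["C1", "C2", "C3", "C4", "C5", "C6"]],
    "LDP": [["C1", "C2", "C3", "C4", "C5", "C6"]],
    # serotonin indole: pyrrole + fused benzene
    "SRO": [
        ["N1", "C2", "C3", "C3A", "C7A"],
        ["C3A", "C4", "C5", "C6", "C7", "C7A"],
    ],
    "5HT": [
        ["N1", "C2", "C3", "C3A", "C7A"],
        ["C3A", "C4", "C5", "C6", "C7", "C7A"],
    ],
}

SITE_FINGERPRINTS: dict[str, frozenset[str]] = {
    "I": frozenset({"A6", "A9", "A11", "B5", "B17", "B21"}),
    "II": frozenset({"B9", "B12", "B16", "B17"}),
    "III": frozenset({"A13", "A14", "A17", "B22"}),
}

#: Fraction of a site fingerprint that must be contacted for assignment.
FINGERPRINT_THRESHOLD = 0.5

ZN_CUTOFF = 2.8
HB_CUTOFF = 3.6
PI_CUTOFF = 3.8
CONTACT_CUTOFF = 4.0

_COORDINATING_ELEMENTS = {"N", "O", "S", "CL", "BR", "F", "I"}
_TETRAHEDRAL_ANGLE = 109.47


@dataclass
class ZincSite:
    zn_position: np.ndarray
    ligand_atoms: list[tuple[AtomRecord, float]]
    coordination_number: int
    geometry: str  # octahedral | tetrahedral | other
    axial_species: str | None


@dataclass
class HBond:
    donor_atom: AtomRecord
    acceptor_atom: AtomRecord
    distance: float
    classification: str  # "HB" | "pi_contact"
    ring_residue: tuple[str, int, str] | None = None  # chain, resnum, resname


@dataclass
class LigandPose:
    ligand_name: str
    site: str  # I | II | III | unassigned
    contact_residues: list[tuple[str, float]] = field(default_factory=list)
    residue_key: tuple[str, int, str] | None = None
    match_fraction: float = 0.0


def classify_zinc_site(
    structure: Structure, cutoff: float = ZN_CUTOFF, model: int = 1
) -> list[ZincSite]:
    """Characterise every Zn²⁺ coordination shell in a model.

    Ligand atoms are N/O/S/halide atoms within ``cutoff`` Å of the zinc.
    The geometry label comes from the coordination number together with
    inter-ligand angle statistics: four ligands with a mean angle within
    15° of 109.47° → tetrahedral; five or six ligands whose angles all
    fall near 90° or 180° (±20°) → octahedral; anything else → other.
    The axial species is a non-His ligand sitting opposite the His
    triad (e.g. the Cl⁻ ion of the R-state shell).
    """
    atoms = structure.model_atoms(model)
    zn_atoms = [a for a in atoms if a.element.upper() == "ZN"]
    sites: list[ZincSite] = []
    for zn in zn_atoms:
        ligands: list[tuple[AtomRecord, float]] = []
        for a in atoms:
            if a is zn or a.element.upper() == "ZN":
                continue
            if a.element.upper() not in _COORDINATING_ELEMENTS:
                continue
            d = float(np.linalg.norm(a.position - zn.position))
            if d <= cutoff:
                ligands.append((a, d))
        ligands.sort(key=lambda t: t[1])
        cn = len(ligands)
        geometry = "other"
        if cn >= 2:
            vecs = np.array(
                [(a.position - zn.position) / d for a, d in ligands]
            )
            angles = []
            for i in range(cn):
                for j in range(i + 1, cn):
                    c = float(np.clip(np.dot(vecs[i], vecs[j]), -1.0, 1.0))
                    angles.append(np.degrees(np.arccos(c)))
            angles = np.array(angles)
            if cn == 4 and abs(angles.mean() - _TETRAHEDRAL_ANGLE) <= 15.0:
                geometry = "tetrahedral"
            elif cn in (5, 6) and np.all(
                (np.abs(angles - 90.0) <= 20.0) | (np.abs(angles - 180.0) <= 20.0)
            ):
                geometry = "octahedral"
        axial = None
        his = [a for a, _ in ligands if a.residue_name == "HIS"]
        non_his = [a for a, _ in ligands if a.residue_name != "HIS"]
        if his and non_his:
            his_dir = np.sum(
                [(a.position - zn.position) for a in his], axis=0
            )
            norm = np.linalg.norm(his_dir)
            if norm > 1e-9:
                his_dir /= norm
                opposite = [
                    a
                    for a in non_his
                    if np.dot(
                        (a.position - zn.position)
                        / np.linalg.norm(a.position - zn.position),
                        his_dir,
                    )
                    < -0.5
                ]
                if len(opposite) == 1:
                    axial = opposite[0].residue_name
        sites.append(
            ZincSite(
                zn_position=zn.position.copy(),
                ligand_atoms=ligands,
                coordination_number=cn,
                geometry=geometry,
                axial_species=axial,
            )
        )
    return sites


def _bond_graph_exclusions(atoms: list[AtomRecord], bond_cut: float = 1.9) -> set:
    """Pairs (i, j) of atom indices within 2 bonds of each other, bonds
    inferred from heavy-atom distances below ``bond_cut`` Å."""
    pos = np.array([a.position for a in atoms])
    tree = cKDTree(pos)
    bonded: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    for i, j in tree.query_pairs(bond_cut):
        bonded[i].add(j)
        bonded[j].add(i)
    excluded: set[tuple[int, int]] = set()
    for i in range(len(atoms)):
        one = bonded[i]
        two = set()
        for j in one:
            two |= bonded[j]
        for j in one | two:
            if j != i:
                excluded.add((min(i, j), max(i, j)))
    return excluded


def detect_contacts(
    structure: Structure,
    hb_cutoff: float = HB_CUTOFF,
    pi_cutoff: float = PI_CUTOFF,
    model: int = 1,
) -> list[HBond]:
    """Distance-criterion hydrogen bonds and π-contacts.

    Hydrogen bonds: N/O heavy-atom pairs within ``hb_cutoff``, excluding
    covalently bonded and 1-3 pairs (bond graph inferred from distances).
    π-contacts: N/O atoms within ``pi_cutoff`` of a 5- or 6-membered
    aromatic ring centroid (rings from per-residue templates), ring's own
    residue excluded.
    """
    atoms = structure.model_atoms(model)
    polar_idx = [i for i, a in enumerate(atoms) if a.element.upper() in ("N", "O")]
    contacts: list[HBond] = []
    if polar_idx:
        excluded = _bond_graph_exclusions(atoms)
        pos = np.array([atoms[i].position for i in polar_idx])
        tree = cKDTree(pos)
        for ii, jj in sorted(tree.query_pairs(hb_cutoff)):
            i, j = polar_idx[ii], polar_idx[jj]
            if (min(i, j), max(i, j)) in excluded:
                continue
            d = float(np.linalg.norm(atoms[i].position - atoms[j].position))
            contacts.append(
                HBond(
                    donor_atom=atoms[i],
                    acceptor_atom=atoms[j],
                    distance=d,
                    classification="HB",
                )
            )

    # rings grouped per residue
    residues: dict[tuple, dict[str, AtomRecord]] = {}
    for a in atoms:
        residues.setdefault(
            (a.chain_id, a.residue_number, a.residue_name), {}
        )[a.atom_name] = a
    for (chain, resnum, resname), resatoms in residues.items():
        for ring_names in RING_TEMPLATES.get(resname, []):
            if not all(n in resatoms for n in ring_names):
                continue
            centroid = np.mean([resatoms[n].position for n in ring_names], axis=0)
            ring_atom = resatoms[ring_names[0]]
            for i in polar_idx:
                a = atoms[i]
                if (a.chain_id, a.residue_number) == (chain, resnum):
                    continue
                d = float(np.linalg.norm(a.position - centroid))
                if d <= pi_cutoff:
                    contacts.append(
                        HBond(
                            donor_atom=a,
                            acceptor_atom=ring_atom,
                            distance=d,
                            classification="pi_contact",
                            ring_residue=(chain, resnum, resname),
                        )
                    )
    return contacts


def _canonical_residue_labels(structure: Structure, model: int) -> dict[tuple, str]:
    """(chain_id, residue_number) -> canonical insulin label like 'A6'/'B22'."""
    labels: dict[tuple, str] = {}
    for mono in identify_monomers(structure, model=model):
        for resnum in mono.a_residues:
            labels[(mono.a_chain_id, resnum)] = f"A{resnum}"
        for resnum in mono.b_residues:
            labels[(mono.b_chain_id, resnum)] = f"B{resnum}"
    return labels


def assign_ligand_sites(
    structure: Structure,
    contact_cutoff: float = CONTACT_CUTOFF,
    threshold: float = FINGERPRINT_THRESHOLD,
    model: int = 1,
) -> list[LigandPose]:
    """Assign each recognised ligand to binding site I, II or III.

    For every ligand residue (phenol, serotonin, dopamine, or hetero
    arginine) the canonical protein residues with any heavy atom within
    ``contact_cutoff`` of any ligand heavy atom are collected; the site
    whose fingerprint is matched in the greatest fraction (>= threshold)
    wins, with ties left unassigned.
    """
    atoms = structure.model_atoms(model)
    labels = _canonical_residue_labels(structure, model)

    ligands: dict[tuple, list[AtomRecord]] = {}
    for a in atoms:
        name = LIGAND_RESNAMES.get(a.residue_name)
        if name is None:
            continue
        if a.residue_name == "ARG" and not a.is_hetero:
            continue  # chain arginine, not a free ligand
        ligands.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(a)

    protein = [a for a in atoms if (a.chain_id, a.residue_number) in labels]
    if not protein:
        return []
    ptree = cKDTree(np.array([a.position for a in protein]))

    poses: list[LigandPose] = []
    for key in sorted(ligands):
        latoms = ligands[key]
        lig_name = LIGAND_RESNAMES[key[2]]
        mins: dict[str, float] = {}
        for a in latoms:
            for j in ptree.query_ball_point(a.position, contact_cutoff):
                p = protein[j]
                d = float(np.linalg.norm(a.position - p.position))
                lab = labels[(p.chain_id, p.residue_number)]
                if d < mins.get(lab, np.inf):
                    mins[lab] = d
        contact_set = set(mins)
        best_site, best_frac = "unassigned", 0.0
        tie = False
        for site, fp in SITE_FINGERPRINTS.items():
            frac = len(contact_set & fp) / len(fp)
            if frac > best_frac:
                best_site, best_frac, tie = site, frac, False
            elif frac == best_frac and frac > 0 and site != best_site:
                tie = True
        if best_frac < threshold or tie:
            best_site = "unassigned"
        poses.append(
            LigandPose(
                ligand_name=lig_name,
                site=best_site,
                contact_residues=sorted(mins.items(), key=lambda t: t[1]),
                residue_key=key,
                match_fraction=best_frac,
            )
        )
    return poses
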