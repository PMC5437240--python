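"""Synthetic inputs for every stage of the pipeline.

Everything the analysis consumes can be generated here with an explicit
seed: idealised insulin hexamer coordinates (torsion-built backbones in
the T / Rf / R recipes, Zn²⁺ coordination shells, serotonin / phenol /
dopamine poses honouring crystallographic anchor distances), Boltzmann
samples from a known 1-D PMF under harmonic biases, λ-series with an
analytic integral, bound-state position clouds, and noisy Hill titration
curves.  Each generator returns its analytic ground truth alongside the
data, so downstream estimators can be tested against exact values.

The hexamer fixtures are geometric test articles, not physical models:
backbones follow ideal torsion recipes, and only the side-chain atoms
that the classifiers actually read (Cys sulfurs, His imidazole nitrogen,
site I / III fingerprint side chains) are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import DEFAULT_TEMPERATURE, rt
from .free_energy import LambdaSeries, UmbrellaWindow, UmbrellaWindowSet
from .geometry import place_atom
from .io import AtomRecord, Structure
from .titration import TitrationSeries, hill_model

__all__ = [
    "FixtureSpec",
    "LigandPlacement",
    "PMFSpec",
    "make_hexamer_fixture",
    "make_insser_t3r3_spec",
    "sample_umbrella_windows",
    "make_ti_series",
    "make_titration",
    "sample_bound_positions",
]

# ---------------------------------------------------------------------------
# sequences and torsion recipes

INSULIN_A = "GIVEQCCTSICSLYQLENYCN"  # A1..A21
INSULIN_B = "FVNQHLCGSHLVEALYLVCGERGFFYTPKT"  # B1..B30

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

HELIX = (-57.0, -47.0)
EXTENDED = (-120.0, 120.0)
# type II' β-turn interior torsions, used at B7-B8 of the T recipe
TURN_II_PRIME = [(60.0, -120.0), (-80.0, 0.0)]

# backbone internal coordinates (Å, degrees)
_BL_N_CA, _BL_CA_C, _BL_C_N, _BL_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7


def _b_chain_torsions(state: str) -> list[tuple[float, float]]:
    """Per-residue (φ, ψ) for B1..B30 in the given conformational state."""
    if state == "R":
        head = [HELIX] * 19
    elif state == "Rf":
        head = [EXTENDED] * 2 + [HELIX] * 17
    elif state == "T":
        head = [EXTENDED] * 6 + TURN_II_PRIME + [HELIX] * 11
    else:
        raise ValueError(f"unknown monomer state {state!r} (use T, Rf or R)")
    return head + [EXTENDED] * 11  # B20-B30 tail


def _build_backbone(torsions: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O coordinates for a chain from sequential torsion geometry."""
    n_res = len(torsions)
    coords: list[dict[str, np.ndarray]] = [dict() for _ in range(n_res)]
    coords[0]["N"] = np.zeros(3)
    coords[0]["CA"] = np.array([_BL_N_CA, 0.0, 0.0])
    theta = math.radians(_ANG_N_CA_C)
    coords[0]["C"] = coords[0]["CA"] + _BL_CA_C * np.array(
        [-math.cos(theta), math.sin(theta), 0.0]
    )
    for i in range(n_res - 1):
        psi = torsions[i][1]
        coords[i + 1]["N"] = place_atom(
            coords[i]["N"], coords[i]["CA"], coords[i]["C"],
            _BL_C_N, _ANG_CA_C_N, psi,
        )
        coords[i + 1]["CA"] = place_atom(
            coords[i]["CA"], coords[i]["C"], coords[i + 1]["N"],
            _BL_N_CA, _ANG_C_N_CA, 180.0,  # trans peptide
        )
        phi_next = torsions[i + 1][0]
        coords[i + 1]["C"] = place_atom(
            coords[i]["C"], coords[i + 1]["N"], coords[i + 1]["CA"],
            _BL_CA_C, _ANG_N_CA_C, phi_next,
        )
        # carbonyl O of residue i, anti to the next N
        coords[i]["O"] = place_atom(
            coords[i]["N"], coords[i]["CA"], coords[i]["C"],
            _BL_C_O, 120.5, psi - 180.0,
        )
    coords[-1]["O"] = place_atom(
        coords[-1]["N"], coords[-1]["CA"], coords[-1]["C"],
        _BL_C_O, 120.5, torsions[-1][1] - 180.0,
    )
    return coords


def _cb_direction(res: dict[str, np.ndarray]) -> np.ndarray:
    """Approximate tetrahedral Cβ direction from N/CA/C."""
    b1 = res["CA"] - res["N"]
    b2 = res["CA"] - res["C"]
    b1 /= np.linalg.norm(b1)
    b2 /= np.linalg.norm(b2)
    u = b1 + b2
    u /= np.linalg.norm(u)
    v = np.cross(b1, b2)
    v /= np.linalg.norm(v)
    d = u + v
    return d / np.linalg.norm(d)


# side-chain stubs the classifiers need: residue -> [(atom, element, dist from CA)]
_SIDECHAIN_STUBS: dict[tuple[str, int], list[tuple[str, str, float]]] = {
    ("A", 6): [("CB", "C", 1.53)],
    ("A", 7): [("CB", "C", 1.53)],
    ("A", 9): [("CB", "C", 1.53), ("OG", "O", 2.4)],
    ("A", 11): [("CB", "C", 1.53)],
    ("A", 13): [("CB", "C", 1.53), ("CD1", "C", 3.0)],
    ("A", 17): [("CB", "C", 1.53), ("OE1", "O", 3.6), ("OE2", "O", 4.0)],
    ("A", 20): [("CB", "C", 1.53), ("SG", "S", 2.8)],
    ("B", 5): [("CB", "C", 1.53), ("NE2", "N", 2.6)],
    ("B", 7): [("CB", "C", 1.53)],
    ("B", 9): [("CB", "C", 1.53), ("OG", "O", 2.4)],
    ("B", 10): [("CB", "C", 1.53), ("NE2", "N", 3.8)],
    ("B", 12): [("CB", "C", 1.53)],
    ("B", 16): [("CB", "C", 1.53)],
    ("B", 17): [("CB", "C", 1.53), ("CD1", "C", 3.0)],
    ("B", 19): [("CB", "C", 1.53), ("SG", "S", 2.8)],
    ("B", 21): [("CB", "C", 1.53), ("OE1", "O", 3.6)],
    ("B", 22): [("CB", "C", 1.53), ("NH1", "N", 4.2)],
}

# Tyr A14 gets a full six-ring (π-stacking partner of the site III clamp)
_TYR_RING_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]


def _tyrosine_ring(res: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Planar phenol ring + OH grafted along the Cβ direction of Tyr."""
    d = _cb_direction(res)
    cb = res["CA"] + 1.53 * d
    axis = d
    # in-plane perpendicular
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    center = cb + (1.5 + 1.39) * axis  # CG at 1.5 from CB, ring radius 1.39
    out: dict[str, np.ndarray] = {"CB": cb}
    for k, name in enumerate(_TYR_RING_NAMES):
        ang = math.radians(60.0 * k + 180.0)  # CG points back toward CB
        out[name] = (
            center
            + 1.39 * math.cos(ang) * axis
            + 1.39 * math.sin(ang) * perp
        )
    out["OH"] = center + (1.39 + 1.36) * axis
    return out


# ---------------------------------------------------------------------------
# ligand templates (heavy atoms, planar rings, Å)


def _indole_template() -> dict[str, np.ndarray]:
    """Serotonin heavy atoms: fused pyrrole/benzene, 5-OH, 3-aminoethyl."""
    apo_h = 1.39 * math.sqrt(3) / 2.0  # hexagon apothem
    hex_center = np.array([-apo_h, 0.0, 0.0])
    atoms = {
        "C3A": np.array([0.0, 0.695, 0.0]),
        "C7A": np.array([0.0, -0.695, 0.0]),
    }
    for name, ang in (("C4", 90.0), ("C5", 150.0), ("C6", 210.0), ("C7", 270.0)):
        a = math.radians(ang)
        atoms[name] = hex_center + 1.39 * np.array([math.cos(a), math.sin(a), 0.0])
    # pyrrole fused on the +x side
    apo_p = 0.695 / math.tan(math.radians(36.0))
    rad_p = 0.695 / math.sin(math.radians(36.0))
    pent_center = np.array([apo_p, 0.0, 0.0])
    for name, ang in (("C3", 72.0), ("C2", 0.0), ("N1", -72.0)):
        a = math.radians(ang)
        atoms[name] = pent_center + rad_p * np.array([math.cos(a), math.sin(a), 0.0])
    # 5-hydroxyl
    d5 = (atoms["C5"] - hex_center) / 1.39
    atoms["O5"] = atoms["C5"] + 1.36 * d5
    # 3-aminoethyl
    d3 = (atoms["C3"] - pent_center) / rad_p
    atoms["C8"] = atoms["C3"] + 1.50 * d3
    up = np.array([d3[0], d3[1], 0.9])
    up /= np.linalg.norm(up)
    atoms["C9"] = atoms["C8"] + 1.53 * up
    dn = np.array([d3[0], d3[1], -0.6])
    dn /= np.linalg.norm(dn)
    atoms["N10"] = atoms["C9"] + 1.48 * dn
    return atoms


def _phenol_template() -> dict[str, np.ndarray]:
    atoms = {}
    for k in range(6):
        a = math.radians(60.0 * k)
        atoms[f"C{k + 1}"] = 1.39 * np.array([math.cos(a), math.sin(a), 0.0])
    atoms["O1"] = atoms["C1"] * (1.39 + 1.36) / 1.39
    return atoms


def _dopamine_template() -> dict[str, np.ndarray]:
    atoms = _phenol_template().copy()
    atoms["O2"] = atoms["C2"] * (1.39 + 1.36) / 1.39
    d = atoms["C4"] / 1.39
    atoms["C7"] = atoms["C4"] + 1.50 * d
    up = np.array([d[0], d[1], 0.9])
    up /= np.linalg.norm(up)
    atoms["C8"] = atoms["C7"] + 1.53 * up
    dn = np.array([d[0], d[1], -0.6])
    dn /= np.linalg.norm(dn)
    atoms["N9"] = atoms["C8"] + 1.48 * dn
    return atoms


_LIGAND_TEMPLATES = {
    "serotonin": ("SRO", _indole_template),
    "phenol": ("IPH", _phenol_template),
    "dopamine": ("LDP", _dopamine_template),
}

# anchor atoms used when docking each ligand (hydroxyl O, amine N, pyrrole ring)
_LIGAND_ANCHOR_ATOMS = {
    "serotonin": {"oh": "O5", "amine": "N10",
                  "pyrrole": ["N1", "C2", "C3", "C3A", "C7A"]},
    "phenol": {"oh": "O1", "amine": None, "pyrrole": None},
    "dopamine": {"oh": "O1", "amine": "N9", "pyrrole": None},
}

# the aminoethyl tails are docked flexibly (rotatable bonds), anchored to
# the ring attachment atom
_LIGAND_FLEX_TAILS = {
    "serotonin": ("C3", [("C8", 1.50), ("C9", 1.53), ("N10", 1.48)]),
    "dopamine": ("C4", [("C7", 1.50), ("C8", 1.53), ("N9", 1.48)]),
}

MIN_NONBONDED = 1.8  # Å; fixture builder clash threshold
_CLEARANCE = 1.9  # Å; soft clearance used during docking
_ANCHOR_WEIGHT = 100.0  # anchors dominate the docking objective


@dataclass
class LigandPlacement:
    name: str  # phenol | serotonin | dopamine
    site: str  # "I" or "III"
    monomer: int  # index of the host monomer, 0..5
    anchors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _LIGAND_TEMPLATES:
            raise ValueError(f"no template for ligand {self.name!r}")
        if self.site not in ("I", "III"):
            raise ValueError("fixture ligands are placed at site I or III")
        defaults = (
            # crystallographic anchors: OH...O=C CysA6 2.42 Å,
            # amine...O=C CysA11 2.75 Å, HisB5 NE2...pyrrole centroid 3.50 Å
            {"oh": 2.42, "amine": 2.75, "pi": 3.50}
            if self.site == "I"
            # surface pocket: OH...Glu A17 OE1, Tyr A14 / Leu A13 clamp
            else {"oh": 3.20, "ring": 3.60, "clamp": 3.90}
        )
        for k, v in defaults.items():
            self.anchors.setdefault(k, v)
        for k, v in self.anchors.items():
            if not 2.0 <= v <= 4.0:
                raise ValueError(f"anchor distance {k}={v} outside [2.0, 4.0] Å")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic hexamer."""

    monomer_states: tuple[str, ...] = ("T",) * 6
    ligands: list[LigandPlacement] = field(default_factory=list)
    zinc: list[tuple[str, str | None]] = field(default_factory=list)
    seed: int = 0
    jitter: float = 0.002  # Å, uniform per coordinate

    def __post_init__(self) -> None:
        if len(self.monomer_states) != 6:
            raise ValueError("a hexamer fixture needs exactly 6 monomer states")
        for s in self.monomer_states:
            if s not in ("T", "Rf", "R"):
                raise ValueError(f"invalid monomer state {s!r}")
        for geom, _ in self.zinc:
            if geom not in ("tetrahedral", "octahedral"):
                raise ValueError(f"invalid zinc geometry {geom!r}")


def make_insser_t3r3_spec(seed: int = 0) -> FixtureSpec:
    """The serotonin-loaded T₃R₃ hexamer: six serotonins (three in the
    internal site I of the R-trimer, three at surface site III) and two
    tetrahedrally coordinated Zn²⁺ with axial chloride."""
    ligands = [LigandPlacement("serotonin", "I", m) for m in (3, 4, 5)]
    ligands += [LigandPlacement("serotonin", "III", m) for m in (0, 1, 2)]
    return FixtureSpec(
        monomer_states=("T", "T", "T", "R", "R", "R"),
        ligands=ligands,
        zinc=[("tetrahedral", "CL"), ("tetrahedral", "CL")],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixture assembly


class _Builder:
    """Accumulates AtomRecords while keeping handles to named atoms."""

    def __init__(self) -> None:
        self.atoms: list[AtomRecord] = []

    def add(self, name, element, resname, chain, resnum, pos, hetero=False) -> AtomRecord:
        rec = AtomRecord(
            atom_name=name,
            element=element,
            residue_name=resname,
            chain_id=chain,
            residue_number=resnum,
            position=np.asarray(pos, float),
            is_hetero=hetero,
        )
        self.atoms.append(rec)
        return rec

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


def _monomer_atoms(state: str) -> tuple[list[tuple], dict]:
    """Build one monomer in its local frame.

    Returns (atom tuples, handles) where handles maps semantic keys
    ('A6:O', 'B10:NE2', ...) to indices into the atom list.
    """
    # A-chain: two helices joined by an extended A9-A11 linker (the loop
    # that lines the phenolic pocket and frees the A6/A11 carbonyls)
    a_torsions = [HELIX] * 8 + [EXTENDED] * 3 + [HELIX] * 10
    b_torsions = _b_chain_torsions(state)
    a_bb = _build_backbone(a_torsions)
    b_bb = _build_backbone(b_torsions)

    # place the A chain antiparallel beside the B-chain helix so that the
    # A20-B19 disulfide sulfurs sit 2.05 Å apart
    b_axis = b_bb[18]["CA"] - b_bb[8]["CA"]
    b_axis /= np.linalg.norm(b_axis)
    a_axis = a_bb[20]["CA"] - a_bb[0]["CA"]
    a_axis /= np.linalg.norm(a_axis)
    rot, _ = Rotation.align_vectors([-b_axis], [a_axis])
    rmat = rot.as_matrix()
    for res in a_bb:
        for k in res:
            res[k] = rmat @ res[k]

    def sg_pos(res: dict) -> np.ndarray:
        return res["CA"] + 2.8 * _cb_direction(res)

    b_centroid = np.mean([r["CA"] for r in b_bb[:19]], axis=0)
    sg_b19 = sg_pos(b_bb[18])
    away = sg_b19 - b_centroid
    away -= np.dot(away, b_axis) * b_axis
    away /= np.linalg.norm(away)

    # spin the A chain about its own (aligned) axis so that the A20 Cβ
    # direction points back toward the B-chain sulfur: the A-chain body
    # then sits on the far side of the disulfide
    ax = -b_axis
    d_a = _cb_direction(a_bb[19])
    d_perp = d_a - np.dot(d_a, ax) * ax
    d_perp /= np.linalg.norm(d_perp)
    tgt = -away
    spin = math.atan2(np.dot(np.cross(d_perp, tgt), ax), np.dot(d_perp, tgt))
    rspin = Rotation.from_rotvec(spin * ax).as_matrix()
    for res in a_bb:
        for k in res:
            res[k] = rspin @ res[k]

    target_sg_a20 = sg_b19 + 2.05 * away
    shift = target_sg_a20 - sg_pos(a_bb[19])
    for res in a_bb:
        for k in res:
            res[k] = res[k] + shift

    # swing the A chain about the disulfide pivot (keeps the S-S distance)
    # to the orientation with the best inter-chain clearance
    b_pos = np.array([r[k] for r in b_bb for k in r])
    b_tree = cKDTree(b_pos)

    def a_positions(chain) -> np.ndarray:
        return np.array([r[k] for r in chain for k in r])

    best_angle, best_clear = 0.0, -np.inf
    for deg in range(0, 360, 15):
        rswing = Rotation.from_rotvec(np.radians(deg) * away).as_matrix()
        moved = (a_positions(a_bb) - target_sg_a20) @ rswing.T + target_sg_a20
        clear = float(b_tree.query(moved)[0].min())
        if clear > best_clear:
            best_angle, best_clear = deg, clear
    if best_angle:
        rswing = Rotation.from_rotvec(np.radians(best_angle) * away).as_matrix()
        for res in a_bb:
            for k in res:
                res[k] = rswing @ (res[k] - target_sg_a20) + target_sg_a20

    atoms: list[tuple] = []  # (name, element, resname, chainkey, resnum, pos)
    handles: dict[str, int] = {}

    def emit(chainkey, chain_bb, sequence):
        for i, res in enumerate(chain_bb, start=1):
            resname = _ONE_TO_THREE[sequence[i - 1]]
            for name in ("N", "CA", "C", "O"):
                atoms.append((name, name[0], resname, chainkey, i, res[name]))
                handles[f"{chainkey}{i}:{name}"] = len(atoms) - 1
            stubs = _SIDECHAIN_STUBS.get((chainkey, i))
            if (chainkey, i) == ("A", 14):
                for name, pos in _tyrosine_ring(res).items():
                    el = "O" if name == "OH" else "C"
                    atoms.append((name, el, resname, chainkey, i, pos))
                    handles[f"A14:{name}"] = len(atoms) - 1
            elif stubs:
                d = _cb_direction(res)
                for name, el, dist in stubs:
                    pos = res["CA"] + dist * d
                    atoms.append((name, el, resname, chainkey, i, pos))
                    handles[f"{chainkey}{i}:{name}"] = len(atoms) - 1

    emit("A", a_bb, INSULIN_A)
    emit("B", b_bb, INSULIN_B)

    # Leu A13 faces the Tyr A14 ring across the site III clamp: its CD1
    # sits on the ring normal, leaving the π-stacking slot in between
    cg = atoms[handles["A14:CG"]][5]
    cd1 = atoms[handles["A14:CD1"]][5]
    cd2 = atoms[handles["A14:CD2"]][5]
    cz = atoms[handles["A14:CZ"]][5]
    normal = np.cross(cd1 - cg, cd2 - cg)
    normal /= np.linalg.norm(normal)
    a_centroid = np.mean([r["CA"] for r in a_bb], axis=0)
    if np.dot(normal, cz - a_centroid) < 0:
        normal = -normal
    idx = handles["A13:CD1"]
    name, el, resname, chainkey, resnum, _ = atoms[idx]
    atoms[idx] = (name, el, resname, chainkey, resnum, cz + 7.5 * normal)

    return atoms, handles


def _dock_ligand(
    lig_name: str,
    template: dict[str, np.ndarray],
    targets: list[tuple[str | list[str], np.ndarray, float]],
    tail_targets: list[tuple[str, np.ndarray, float]],
    protein_pos: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Place a ligand honouring distance anchors without steric clashes.

    The aromatic scaffold is docked as a rigid body (6 DOF) against the
    ``targets`` anchors; the aminoethyl tail, when the ligand has one,
    is then built flexibly (its bonds are rotatable) to satisfy the
    ``tail_targets`` anchors.  Anchor keys may be atom names or lists of
    ring atom names (anchored via the ring centroid).  Raises when the
    anchor set cannot be met with every ligand atom at least 1.8 Å from
    the protein.
    """
    tail_spec = _LIGAND_FLEX_TAILS.get(lig_name)
    tail_names: list[str] = [n for n, _ in tail_spec[1]] if tail_spec else []
    rigid_names = [n for n in template if n not in tail_names]
    base = np.array([template[n] for n in rigid_names])
    base -= base.mean(axis=0)
    tree = cKDTree(protein_pos)

    # endpoint-first: fix a clash-free terminal-amine position on the
    # anchor sphere, then keep the tail attachment within chain reach
    reach_windows: list[tuple[np.ndarray, float, float]] = []
    endpoint: np.ndarray | None = None
    if tail_spec and tail_targets:
        attach = tail_spec[0]
        total_reach = sum(L for _, L in tail_spec[1])
        point, dist = tail_targets[0][1], tail_targets[0][2]
        endpoint = _clearest_sphere_point(
            point, dist, tree, toward=targets[0][1] if targets else None
        )
        reach_windows.append(
            (endpoint, 0.55 * total_reach, 0.92 * total_reach)
        )
    else:
        attach = None

    def lig_coords(params: np.ndarray) -> np.ndarray:
        return base @ Rotation.from_rotvec(params[:3]).as_matrix().T + params[3:]

    def anchor_point(coords: np.ndarray, key) -> np.ndarray:
        if isinstance(key, list):
            idx = [rigid_names.index(n) for n in key]
            return coords[idx].mean(axis=0)
        return coords[rigid_names.index(key)]

    def anchor_residuals(params: np.ndarray) -> np.ndarray:
        coords = lig_coords(params)
        res = [
            np.linalg.norm(anchor_point(coords, k) - p) - d
            for k, p, d in targets
        ]
        for point, dmin_w, dmax_w in reach_windows:
            r = np.linalg.norm(anchor_point(coords, attach) - point)
            res.append(max(0.0, r - dmax_w) + max(0.0, dmin_w - r))
        return np.array(res)

    def clearance_residuals(params: np.ndarray) -> np.ndarray:
        dmin, _ = tree.query(lig_coords(params))
        return np.clip(_CLEARANCE - dmin, 0.0, None)

    anchor_pts = [p for _, p, _ in targets] + [w[0] for w in reach_windows]
    centroid_target = np.mean(anchor_pts, axis=0)
    outward = centroid_target - protein_pos.mean(axis=0)
    outward /= max(np.linalg.norm(outward), 1e-9)
    best = None
    for _ in range(60):
        x0 = np.concatenate(
            [
                rng.uniform(-math.pi, math.pi, 3),
                centroid_target
                + outward * rng.uniform(0.5, 3.0)
                + rng.normal(0.0, 2.0, 3),
            ]
        )
        sol = least_squares(anchor_residuals, x0, xtol=1e-12, ftol=1e-12)
        if np.any(clearance_residuals(sol.x) > 0):
            sol = least_squares(
                lambda p: np.concatenate(
                    [
                        math.sqrt(_ANCHOR_WEIGHT) * anchor_residuals(p),
                        clearance_residuals(p),
                    ]
                ),
                sol.x,
                xtol=1e-12,
                ftol=1e-12,
            )
        coords = lig_coords(sol.x)
        anchor_err = float(np.max(np.abs(anchor_residuals(sol.x))))
        dmin = float(tree.query(coords)[0].min())
        score = (round(anchor_err, 4), -dmin)
        if best is None or score < best[0]:
            best = (score, coords, anchor_err, dmin)
        if anchor_err < 1e-3 and dmin >= MIN_NONBONDED + 0.02:
            break
    _, coords, anchor_err, dmin = best
    if anchor_err > 0.01 or dmin < MIN_NONBONDED:
        raise ValueError(
            f"infeasible ligand anchor set (residual {anchor_err:.3f} Å, "
            f"closest protein approach {dmin:.2f} Å)"
        )
    placed = {n: coords[i] for i, n in enumerate(rigid_names)}

    if tail_spec:
        placed.update(
            _solve_tail(tail_spec, placed, tail_targets, tree, rng, endpoint)
        )
    return placed


def _clearest_sphere_point(
    point: np.ndarray,
    dist: float,
    tree: cKDTree,
    toward: np.ndarray | None = None,
    n: int = 512,
) -> np.ndarray:
    """A clash-free point at ``dist`` from ``point`` (Fibonacci sphere scan).

    Among candidates with clearance >= 2.05 Å the one closest to
    ``toward`` is returned (falling back to the maximum-clearance point),
    so a flexible tail can end near where its ligand body will sit."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    best_p, best_d = None, -np.inf
    best_near, best_near_d = None, np.inf
    for k in range(n):
        z = 1.0 - 2.0 * (k + 0.5) / n
        r = math.sqrt(1.0 - z * z)
        th = golden * k
        cand = point + dist * np.array([r * math.cos(th), r * math.sin(th), z])
        d = float(tree.query(cand)[0])
        if d > best_d:
            best_p, best_d = cand, d
        if toward is not None and d >= 2.05:
            dt = float(np.linalg.norm(cand - toward))
            if dt < best_near_d:
                best_near, best_near_d = cand, dt
    return best_near if best_near is not None else best_p


def _solve_tail(
    tail_spec: tuple[str, list[tuple[str, float]]],
    rigid: dict[str, np.ndarray],
    tail_targets: list[tuple[str, np.ndarray, float]],
    tree: cKDTree,
    rng: np.random.Generator,
    endpoint: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Build the flexible aminoethyl tail: bond lengths fixed, torsions
    free, optional anchor on the terminal amine, clash clearance kept."""
    attach_name, chain = tail_spec
    attach = rigid[attach_name]
    rigid_pos = np.array(list(rigid.values()))
    centroid = rigid_pos.mean(axis=0)
    out_dir = attach - centroid
    out_dir /= np.linalg.norm(out_dir)
    n_atoms = len(chain)
    names = [n for n, _ in chain]
    lengths = np.array([L for _, L in chain])
    target_map = {k: (p, d) for k, p, d in tail_targets}

    def coords_of(x: np.ndarray) -> np.ndarray:
        return x.reshape(n_atoms, 3)

    def residuals(x: np.ndarray) -> np.ndarray:
        pos = coords_of(x)
        res = []
        prev = attach
        for i in range(n_atoms):
            res.append(10.0 * (np.linalg.norm(pos[i] - prev) - lengths[i]))
            prev = pos[i]
        # 1-3 separation keeps bond angles open
        chain_pts = [attach] + [pos[i] for i in range(n_atoms)]
        for i in range(len(chain_pts) - 2):
            d13 = np.linalg.norm(chain_pts[i + 2] - chain_pts[i])
            res.append(5.0 * max(0.0, 2.35 - d13))
        for i, name in enumerate(names):
            if name in target_map:
                point, dist = target_map[name]
                res.append(10.0 * (np.linalg.norm(pos[i] - point) - dist))
            if endpoint is not None and i == n_atoms - 1:
                res.append(10.0 * np.linalg.norm(pos[i] - endpoint))
            dmin = tree.query(pos[i])[0]
            res.append(max(0.0, _CLEARANCE - dmin))
            # stay clear of the ligand's own ring (bonded neighbours exempt)
            d_ring = np.linalg.norm(rigid_pos - pos[i], axis=1).min()
            if i > 0:
                res.append(max(0.0, 2.0 - d_ring))
        return np.array(res)

    total_reach = float(lengths.sum())
    endpoints: list[np.ndarray] = []
    if tail_targets:
        # candidate amine endpoints on the anchor sphere, reachable from
        # the attachment and clear of the protein
        point, dist = tail_targets[0][1], tail_targets[0][2]
        golden = math.pi * (3.0 - math.sqrt(5.0))
        cands = []
        for k in range(256):
            z = 1.0 - 2.0 * (k + 0.5) / 256.0
            r = math.sqrt(1.0 - z * z)
            th = golden * k
            cand = point + dist * np.array(
                [r * math.cos(th), r * math.sin(th), z]
            )
            span = float(np.linalg.norm(cand - attach))
            if not 0.45 * total_reach <= span <= 0.95 * total_reach:
                continue
            clear = float(tree.query(cand)[0])
            if clear < _CLEARANCE:
                continue
            cands.append((clear, tuple(cand)))
        cands.sort(reverse=True)
        endpoints = [np.array(c) for _, c in cands[:10]]
    if endpoint is not None and not endpoints:
        endpoints = [endpoint]
    if not endpoints:
        endpoints = [attach + 0.9 * total_reach * out_dir]

    best = None
    for trial in range(40):
        endpoint = endpoints[trial % len(endpoints)]
        x0 = []
        cum = np.cumsum(lengths)
        for i in range(n_atoms):
            frac = cum[i] / total_reach
            x0.append(
                attach + frac * (endpoint - attach) + rng.normal(0, 0.15, 3)
            )
        sol = least_squares(residuals, np.ravel(x0), xtol=1e-12, ftol=1e-12)
        pos = coords_of(sol.x)
        errs = []
        prev = attach
        for i in range(n_atoms):
            errs.append(abs(np.linalg.norm(pos[i] - prev) - lengths[i]))
            prev = pos[i]
        for i, name in enumerate(names):
            if name in target_map:
                point, dist = target_map[name]
                errs.append(abs(np.linalg.norm(pos[i] - point) - dist))
        err = max(errs)
        dmin = float(min(tree.query(pos[i])[0] for i in range(n_atoms)))
        score = (round(err, 4), -dmin)
        if best is None or score < best[0]:
            best = (score, pos, err, dmin)
        if err < 1e-3 and dmin >= MIN_NONBONDED + 0.02:
            break
    _, pos, err, dmin = best
    if err > 0.01 or dmin < MIN_NONBONDED:
        raise ValueError(
            f"infeasible tail anchor set (residual {err:.3f} Å, closest "
            f"protein approach {dmin:.2f} Å)"
        )
    return {n: pos[i] for i, n in enumerate(names)}


_A_CHAIN_IDS = "ACEGIK"
_B_CHAIN_IDS = "BDFHJL"


def make_hexamer_fixture(spec: FixtureSpec) -> Structure:
    """Build a synthetic insulin hexamer as a :class:`Structure`.

    Six torsion-built monomers are arranged with 3-fold symmetry in two
    trimers (monomers 0-2 top, 3-5 bottom); Zn²⁺ ions with ideal
    tetrahedral or octahedral shells sit on the symmetry axis, and
    ligands are docked at sites I / III honouring the requested anchor
    distances.  Deterministic for a given (spec, seed); a final uniform
    jitter of amplitude ``spec.jitter`` Å (seeded) makes replicate
    fixtures distinguishable without moving any classification.
    """
    # docking restarts use a fixed stream so the placed geometry is
    # identical across fixture seeds; the seed drives only the jitter
    rng = np.random.default_rng(910731)
    jitter_rng = np.random.default_rng(spec.seed)
    builder = _Builder()
    radius, z_off = 30.0, 16.0
    handles_per_monomer: list[dict[str, int]] = []
    first_atom_index: list[int] = []

    for m, state in enumerate(spec.monomer_states):
        atoms, handles = _monomer_atoms(state)
        top = m < 3
        azimuth = math.radians(120.0 * (m % 3) + (0.0 if top else 60.0))
        rz = Rotation.from_euler("z", azimuth).as_matrix()
        flip = (
            np.eye(3)
            if top
            else Rotation.from_euler("x", math.pi).as_matrix()
        )
        rot = rz @ flip
        center = rot @ np.array([radius, 0.0, 0.0]) + np.array(
            [0.0, 0.0, z_off if top else -z_off]
        )
        local = np.array([a[5] for a in atoms])
        local -= local.mean(axis=0)
        placed = local @ rot.T + center
        first_atom_index.append(len(builder.atoms))
        for (name, el, resname, chainkey, resnum, _), pos in zip(atoms, placed):
            chain = _A_CHAIN_IDS[m] if chainkey == "A" else _B_CHAIN_IDS[m]
            builder.add(name, el, resname, chain, resnum, pos)
        handles_per_monomer.append(handles)

    def monomer_atom(m: int, key: str) -> AtomRecord:
        return builder.atoms[first_atom_index[m] + handles_per_monomer[m][key]]

    # zinc shells on the 3-fold axis, one per requested trimer
    water_serial = 1
    for t, (geom, axial) in enumerate(spec.zinc[:2]):
        top = t == 0
        sign = 1.0 if top else -1.0
        zn_pos = np.array([0.0, 0.0, sign * z_off])
        builder.add("ZN", "ZN", "ZN", "W", 100 + t, zn_pos, hetero=True)
        axis = np.array([0.0, 0.0, sign])
        members = (0, 1, 2) if top else (3, 4, 5)
        if geom == "tetrahedral":
            # axial species along the axis, His triad at 109.47° from it
            if axial:
                builder.add(
                    axial[:2], "CL" if axial.upper().startswith("CL") else "O",
                    axial.upper()[:3], "W", 200 + t,
                    zn_pos + 2.2 * axis, hetero=True,
                )
            for k, m in enumerate(members):
                ang = math.radians(120.0 * k)
                direction = (
                    math.cos(math.radians(109.47)) * axis
                    + math.sin(math.radians(109.47))
                    * np.array([math.cos(ang), math.sin(ang), 0.0])
                )
                ne2 = monomer_atom(m, "B10:NE2")
                ne2.position = zn_pos + 2.1 * direction
        else:  # octahedral: His triad + three waters on orthogonal axes
            e = [
                np.array([1.0, 0.0, 0.0]),
                np.array([0.0, 1.0, 0.0]),
                axis,
            ]
            for k, m in enumerate(members):
                ne2 = monomer_atom(m, "B10:NE2")
                ne2.position = zn_pos + 2.1 * e[k]
            for k in range(3):
                builder.add(
                    "O", "O", "HOH", "W", 300 + 10 * t + k,
                    zn_pos - 2.1 * e[k], hetero=True,
                )
                water_serial += 1

    # ligands
    lig_resnum = 1
    for lig in spec.ligands:
        resname, template_fn = _LIGAND_TEMPLATES[lig.name]
        template = template_fn()
        anchors = _LIGAND_ANCHOR_ATOMS[lig.name]
        m = lig.monomer
        targets: list[tuple[str | list[str], np.ndarray, float]] = []
        tail_targets: list[tuple[str, np.ndarray, float]] = []
        if lig.site == "I":
            targets.append(
                (anchors["oh"], monomer_atom(m, "A6:O").position, lig.anchors["oh"])
            )
            if anchors["amine"] and lig.name in _LIGAND_FLEX_TAILS:
                tail_targets.append(
                    (anchors["amine"], monomer_atom(m, "A11:O").position,
                     lig.anchors["amine"])
                )
        else:  # site III
            targets.append(
                (anchors["oh"], monomer_atom(m, "A17:OE1").position,
                 lig.anchors["oh"])
            )
            ring_key = anchors["pyrrole"] or list(template)[:6]
            targets.append(
                (ring_key, monomer_atom(m, "A14:CZ").position,
                 lig.anchors["ring"])
            )
            targets.append(
                (ring_key, monomer_atom(m, "A13:CD1").position,
                 lig.anchors["clamp"])
            )
        placed = _dock_ligand(
            lig.name, template, targets, tail_targets, builder.positions(), rng
        )
        for name, pos in placed.items():
            builder.add(name, name[0], resname, "X", lig_resnum, pos, hetero=True)
        # the His B5 imidazole nitrogen caps the pyrrole face at site I
        if lig.site == "I" and anchors["pyrrole"]:
            ring = np.array([placed[n] for n in anchors["pyrrole"]])
            centroid = ring.mean(axis=0)
            normal = np.cross(ring[1] - ring[0], ring[2] - ring[0])
            normal /= np.linalg.norm(normal)
            cand = [centroid + lig.anchors["pi"] * normal,
                    centroid - lig.anchors["pi"] * normal]
            tree = cKDTree(builder.positions())
            dists = [tree.query(c)[0] for c in cand]
            ne2 = monomer_atom(m, "B5:NE2")
            ne2.position = cand[int(np.argmax(dists))]
        lig_resnum += 1

    # seeded jitter (uniform, well under any classification tolerance)
    if spec.jitter > 0:
        jit = jitter_rng.uniform(-spec.jitter, spec.jitter, (len(builder.atoms), 3))
        for a, dx in zip(builder.atoms, jit):
            a.position = a.position + dx

    _check_clashes(builder.atoms)
    return Structure(atoms=builder.atoms, models=1, source_format="PDB")


def _check_clashes(atoms: list[AtomRecord]) -> None:
    """Raise if non-bonded heavy atoms approach closer than 1.8 Å."""
    pos = np.array([a.position for a in atoms])
    tree = cKDTree(pos)
    offending = []
    for i, j in tree.query_pairs(MIN_NONBONDED):
        a, b = atoms[i], atoms[j]
        same_res = (a.chain_id, a.residue_number) == (b.chain_id, b.residue_number)
        sequential = a.chain_id == b.chain_id and abs(
            a.residue_number - b.residue_number
        ) == 1
        if not (same_res or sequential):
            offending.append(
                f"{a.chain_id}/{a.residue_number}/{a.atom_name} - "
                f"{b.chain_id}/{b.residue_number}/{b.atom_name}"
            )
    if offending:
        raise ValueError(
            "fixture has steric clashes (< 1.8 Å): " + "; ".join(offending[:10])
        )


# ---------------------------------------------------------------------------
# 1-D PMFs and umbrella sampling emulation


@dataclass
class PMFSpec:
    """A known 1-D potential of mean force for umbrella emulation.

    Forms: ``harmonic`` (½·curvature·(x−center)², for PMF-recovery
    tests), ``gaussian_well`` (−depth·exp(−(x−center)²/2width²), a bound
    well decaying to a flat plateau at 0, for the full binding chain),
    ``double_well`` (depth·(((x−center)/width)²−1)²), and ``table``
    (linear interpolation of tabulated x, U)."""

    form: str = "gaussian_well"
    depth: float = 3.0  # kcal/mol
    width: float = 0.5  # coordinate units
    center: float = 0.0
    curvature: float = 1.0  # kcal/mol per unit² (harmonic form)
    table: tuple[np.ndarray, np.ndarray] | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.form not in ("harmonic", "gaussian_well", "double_well", "table"):
            raise ValueError(f"unknown PMF form {self.form!r}")
        if self.form == "table" and self.table is None:
            raise ValueError("table form needs tabulated (x, U)")

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            return 0.5 * self.curvature * (x - self.center) ** 2
        if self.form == "gaussian_well":
            return -self.depth * np.exp(
                -((x - self.center) ** 2) / (2.0 * self.width**2)
            )
        if self.form == "double_well":
            return self.depth * (((x - self.center) / self.width) ** 2 - 1.0) ** 2
        xs, us = self.table
        return np.interp(x, xs, us)

    def analytic_well_depth(self) -> float:
        """W₀ of the analytic PMF (bound minimum minus plateau at 0)."""
        if self.form == "gaussian_well":
            return -self.depth
        raise ValueError(f"no closed-form well depth for form {self.form!r}")


def sample_umbrella_windows(
    pmf: PMFSpec,
    centers: list[float] | np.ndarray,
    spring_k: float,
    n_per_window: int,
    seed: int = 0,
) -> UmbrellaWindowSet:
    """Draw Boltzmann samples from ``pmf`` under harmonic biases.

    Each window's density ∝ exp(−[U(x) + ½k(x−c)²]/RT) is inverted by
    inverse-CDF on a fine grid; deterministic per seed.  Raises if the
    spring is too weak to confine samples within the grid.
    """
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    if spring_k <= 0:
        raise ValueError("spring constant must be positive")
    centers = np.asarray(centers, dtype=float)
    kt = rt(pmf.temperature)
    pad = max(6.0 * math.sqrt(kt / spring_k), 4.0 * pmf.width, 1.0)
    lo = float(centers.min()) - pad
    hi = float(centers.max()) + pad
    if pmf.form == "table":
        # a tabulated PMF is only defined on its support
        lo = max(lo, float(np.min(pmf.table[0])))
        hi = min(hi, float(np.max(pmf.table[0])))
    grid = np.linspace(lo, hi, 8001)
    u_grid = pmf.energy(grid)
    rng = np.random.default_rng(seed)
    windows: list[UmbrellaWindow] = []
    for c in centers:
        total = u_grid + 0.5 * spring_k * (grid - c) ** 2
        w = np.exp(-(total - total.min()) / kt)
        edge_mass = w[:40].sum() + w[-40:].sum()
        if edge_mass > 1e-6 * w.sum():
            raise ValueError(
                f"spring k={spring_k} too weak to confine window at {c} "
                "within the sampling grid"
            )
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2.0)])
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(center=float(c), spring_k=spring_k, samples=samples))
    return UmbrellaWindowSet(windows=windows, temperature=pmf.temperature)


# ---------------------------------------------------------------------------
# TI series, titration curves, bound-state clouds


def make_ti_series(
    a: float = 0.0,
    b: float = 0.0,
    c: float = 0.0,
    n_lambda: int = 21,
    noise_sem: float = 0.0,
    seed: int = 0,
) -> tuple[LambdaSeries, float]:
    """Toy coupling λ-series with an analytic integral.

    ⟨∂U/∂λ⟩ = a + bλ + c·sin(πλ), whose integral over [0, 1] is
    a + b/2 + 2c/π; Gaussian noise of standard deviation ``noise_sem``
    is added per point and reported as the SEM column.
    Returns (series, analytic ΔG).
    """
    if n_lambda < 2:
        raise ValueError("need at least 2 lambda points")
    lam = np.linspace(0.0, 1.0, n_lambda)
    dudl = a + b * lam + c * np.sin(math.pi * lam)
    if noise_sem > 0:
        rng = np.random.default_rng(seed)
        dudl = dudl + rng.normal(0.0, noise_sem, n_lambda)
    series = LambdaSeries(
        lambdas=lam,
        dudl_mean=dudl,
        dudl_sem=np.full(n_lambda, float(noise_sem)),
    )
    analytic = a + b / 2.0 + 2.0 * c / math.pi
    return series, analytic


def make_titration(
    kd: float,
    bmax: float,
    h: float,
    concentrations: np.ndarray | list[float],
    noise_sd: float = 0.005,
    n_replicates: int = 1,
    seed: int = 0,
    ligand_name: str = "",
) -> list[TitrationSeries]:
    """Noisy Hill-model titration curves, one series per replicate.

    ΔA = B_max c^h/(K_d^h + c^h) + N(0, noise_sd) per point; replicate
    ``i`` uses the sub-seed ``seed + i``, so replicate sets are stable
    under extension.
    """
    conc = np.asarray(concentrations, dtype=float)
    out: list[TitrationSeries] = []
    for i in range(n_replicates):
        rng = np.random.default_rng(seed + i)
        clean = hill_model(conc, kd, bmax, h)
        noisy = clean + (rng.normal(0.0, noise_sd, conc.size) if noise_sd > 0 else 0.0)
        out.append(
            TitrationSeries(
                concentrations=conc.copy(),
                delta_a=np.asarray(noisy, dtype=float),
                replicate_id=i,
                ligand_name=ligand_name,
            )
        )
    return out


def sample_bound_positions(
    covariance: np.ndarray, n: int, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Multivariate-Gaussian bound-ligand centres plus the analytic
    effective volume (2πe)^{3/2}|Σ|^{1/2} (Å³)."""
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError("covariance must be 3x3")
    eig = np.linalg.eigvalsh(cov)
    if np.any(eig <= 0):
        raise ValueError("covariance must be positive definite")
    rng = np.random.default_rng(seed)
    positions = rng.multivariate_normal(np.zeros(3), cov, size=n)
    analytic = (2.0 * math.pi * math.e) ** 1.5 * math.sqrt(
        float(np.linalg.det(cov))
    )
    return positions, analytic
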