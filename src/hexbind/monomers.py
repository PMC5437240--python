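"""Organising parsed atoms into insulin monomers.

An insulin monomer is an A-chain (21 residues, canonical A1..A21) paired
with a B-chain (30 residues, B1..B30) through the inter-chain
Cys A20 - Cys B19 disulfide.  Pairing is decided purely geometrically,
by the nearest S-S sulfur pair under a cutoff, so the function works on
single monomers, dimers and full hexamers alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral
from .io import AtomRecord, Structure

logger = logging.getLogger(__name__)

__all__ = ["InsulinMonomer", "identify_monomers", "backbone_dihedrals"]

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Default S-S distance cutoff (Å) for recognising the A20-B19 disulfide.
SS_CUTOFF = 3.0


@dataclass
class InsulinMonomer:
    """One insulin molecule: A-chain + B-chain residue maps.

    Residue maps are keyed by canonical number (A1..A21 / B1..B30); each
    value maps atom name -> :class:`AtomRecord`.
    """

    a_chain_id: str
    b_chain_id: str
    a_residues: dict[int, dict[str, AtomRecord]] = field(default_factory=dict)
    b_residues: dict[int, dict[str, AtomRecord]] = field(default_factory=dict)
    dimer_partner: "InsulinMonomer | None" = None

    def atom(self, chain: str, resnum: int, name: str) -> AtomRecord | None:
        res = (self.a_residues if chain.upper() == "A" else self.b_residues).get(resnum)
        if res is None:
            return None
        return res.get(name)

    def residues(self, chain: str) -> dict[int, dict[str, AtomRecord]]:
        return self.a_residues if chain.upper() == "A" else self.b_residues

    def all_atoms(self) -> list[AtomRecord]:
        out: list[AtomRecord] = []
        for resmap in (self.a_residues, self.b_residues):
            for atoms in resmap.values():
                out.extend(atoms.values())
        return out

    def has_backbone(self, chain: str, first: int, last: int) -> bool:
        resmap = self.residues(chain)
        for i in range(first, last + 1):
            res = resmap.get(i)
            if res is None or not {"N", "CA", "C"} <= res.keys():
                return False
        return True


def _chain_residue_map(
    atoms: list[AtomRecord],
) -> dict[str, dict[int, dict[str, AtomRecord]]]:
    """chain id -> residue number -> atom name -> record (amino acids only)."""
    chains: dict[str, dict[int, dict[str, AtomRecord]]] = {}
    for a in atoms:
        if a.residue_name not in _AMINO_ACIDS:
            continue
        chains.setdefault(a.chain_id, {}).setdefault(a.residue_number, {})[
            a.atom_name
        ] = a
    return chains


def _canonicalize(residues: dict[int, dict[str, AtomRecord]]) -> dict[int, dict]:
    """Renumber a chain to 1-based canonical numbering when the author
    numbering does not already start at 1."""
    if not residues:
        return residues
    start = min(residues)
    if start == 1:
        return residues
    return {num - start + 1: res for num, res in residues.items()}


def identify_monomers(
    structure: Structure, model: int = 1, ss_cutoff: float = SS_CUTOFF
) -> list[InsulinMonomer]:
    """Group the chains of a structure into insulin monomers.

    A-chains and B-chains are told apart by length (21 vs 30 residues,
    with slack for partially resolved termini) and paired through the
    nearest Cys A20 SG - Cys B19 SG pair within ``ss_cutoff`` Å.
    Chains that cannot be paired are reported via a warning and omitted.
    Monomers are returned sorted by A-chain id.
    """
    chains = _chain_residue_map(structure.model_atoms(model))
    a_chains: dict[str, dict[int, dict]] = {}
    b_chains: dict[str, dict[int, dict]] = {}
    for cid, residues in chains.items():
        residues = _canonicalize(residues)
        n = len(residues)
        if n == 0:
            continue
        if n <= 23:
            a_chains[cid] = residues
        else:
            b_chains[cid] = residues

    pairs: list[tuple[float, str, str]] = []
    for aid, ares in a_chains.items():
        sg_a = ares.get(20, {}).get("SG")
        if sg_a is None:
            continue
        for bid, bres in b_chains.items():
            sg_b = bres.get(19, {}).get("SG")
            if sg_b is None:
                continue
            d = float(np.linalg.norm(sg_a.position - sg_b.position))
            if d <= ss_cutoff:
                pairs.append((d, aid, bid))
    pairs.sort()

    used_a: set[str] = set()
    used_b: set[str] = set()
    monomers: list[InsulinMonomer] = []
    for _, aid, bid in pairs:
        if aid in used_a or bid in used_b:
            continue
        used_a.add(aid)
        used_b.add(bid)
        monomers.append(
            InsulinMonomer(
                a_chain_id=aid,
                b_chain_id=bid,
                a_residues=a_chains[aid],
                b_residues=b_chains[bid],
            )
        )
    unpaired = (set(a_chains) - used_a) | (set(b_chains) - used_b)
    if unpaired:
        logger.warning(
            "unpaired chains omitted (no Cys A20-B19 S-S under %.2f Å): %s",
            ss_cutoff,
            ", ".join(sorted(unpaired)),
        )
    monomers.sort(key=lambda m: m.a_chain_id)
    return monomers


def _chain_dihedrals(
    residues: dict[int, dict[str, AtomRecord]],
) -> dict[int, tuple[float | None, float | None]]:
    out: dict[int, tuple[float | None, float | None]] = {}
    nums = sorted(residues)
    for i in nums:
        res = residues[i]
        prev = residues.get(i - 1)
        nxt = residues.get(i + 1)
        phi = psi = None
        if {"N", "CA", "C"} <= res.keys():
            if prev is not None and "C" in prev:
                phi = dihedral(
                    prev["C"].position,
                    res["N"].position,
                    res["CA"].position,
                    res["C"].position,
                )
            if nxt is not None and "N" in nxt:
                psi = dihedral(
                    res["N"].position,
                    res["CA"].position,
                    res["C"].position,
                    nxt["N"].position,
                )
        out[i] = (phi, psi)
    return out


def backbone_dihedrals(
    monomer: InsulinMonomer,
) -> dict[str, dict[int, tuple[float | None, float | None]]]:
    """Per-residue (φ, ψ) in degrees for both chains of a monomer.

    φ is undefined (None) for the first residue of a chain, ψ for the
    last; any residue with missing backbone atoms gets None for the
    affected torsions.
    """
    return {
        "A": _chain_dihedrals(monomer.a_residues),
        "B": _chain_dihedrals(monomer.b_residues),
    }
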