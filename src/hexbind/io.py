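"""Reading and writing of atomic coordinate files.

Thin wrapper around :mod:`gemmi` that flattens PDB / mmCIF content into a
list of plain :class:`AtomRecord` objects — the in-memory currency of the
rest of the package.  Multi-model files are kept as frames (``model``
index on every atom, contiguous from 1).  Waters and hetero atoms are
preserved; anisotropic records are ignored.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["AtomRecord", "Structure", "read_structure", "write_pdb"]


@dataclass
class AtomRecord:
    """One atom of one model: author naming/numbering, position in Å."""

    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    model: int = 1
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(
                f"atom {self.atom_name}: position must be a finite 3-vector"
            )
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]"
            )

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class Structure:
    """A parsed coordinate file: flat atom list plus frame count."""

    atoms: list[AtomRecord] = field(default_factory=list)
    models: int = 1
    source_format: str = "PDB"

    def model_atoms(self, model: int = 1) -> list[AtomRecord]:
        return [a for a in self.atoms if a.model == model]

    def chain_ids(self, model: int = 1) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.model_atoms(model):
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def positions(self, model: int = 1) -> np.ndarray:
        return np.array([a.position for a in self.model_atoms(model)], dtype=float)

    def find_atoms(
        self,
        model: int = 1,
        chain_id: str | None = None,
        residue_number: int | None = None,
        residue_name: str | None = None,
        atom_name: str | None = None,
    ) -> list[AtomRecord]:
        out = []
        for a in self.model_atoms(model):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            out.append(a)
        return out


_FORMAT_MAP = {
    "PDB": gemmi.CoorFormat.Pdb,
    "MMCIF": gemmi.CoorFormat.Mmcif,
    "AUTO": gemmi.CoorFormat.Detect,
}


def _dedup_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one atom per (model, chain, residue, name): highest occupancy,
    ties broken in favour of altloc 'A' (then lexicographically)."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.model, a.chain_id, a.residue_number, a.residue_name, a.atom_name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        else:
            if (a.occupancy, a.altloc == "A", -ord(a.altloc or "z")) > (
                cur.occupancy,
                cur.altloc == "A",
                -ord(cur.altloc or "z"),
            ):
                best[key] = a
    return [best[k] for k in order]


def read_structure(path: str | os.PathLike, format: str = "auto") -> Structure:
    """Parse a PDB or mmCIF coordinate file.

    Parameters
    ----------
    path : path to the coordinate file.
    format : ``"PDB"``, ``"mmCIF"`` or ``"auto"`` (detect from contents).

    Returns
    -------
    Structure with all atoms of all models; where a file carries multiple
    altlocs for one atom, the highest-occupancy conformer is retained
    (ties resolved toward altloc ``A``).
    """
    fmt_key = format.upper().replace("MMCIF", "MMCIF")
    if fmt_key not in _FORMAT_MAP:
        raise ValueError(f"unknown format {format!r}; use PDB, mmCIF or auto")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(path, format=_FORMAT_MAP[fmt_key])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc

    source_format = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    atoms: list[AtomRecord] = []
    for imodel, model in enumerate(st, start=1):
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for atom in residue:
                    atoms.append(
                        AtomRecord(
                            atom_name=atom.name,
                            element=atom.element.name,
                            residue_name=residue.name,
                            chain_id=chain.name,
                            residue_number=residue.seqid.num,
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            occupancy=min(max(atom.occ, 0.0), 1.0),
                            altloc=atom.altloc.strip() or "",
                            model=imodel,
                            is_hetero=het,
                        )
                    )
    if not atoms:
        raise ValueError(f"{path}: no atoms parsed")

    if source_format == "PDB":
        with open(path, "rb") as fh:
            tail = fh.read().rstrip()
        if not tail.endswith(b"END") and b"\nEND" not in tail[-200:]:
            logger.warning("%s: no END record; parsed permissively", path)

    atoms = _dedup_altlocs(atoms)
    return Structure(atoms=atoms, models=len(st), source_format=source_format)


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write a :class:`Structure` as a PDB file (0.001 Å precision)."""
    st = gemmi.Structure()
    st.name = "hexbind"
    for imodel in range(1, structure.models + 1):
        # group first: gemmi containers copy on add, so residues must be
        # fully populated before insertion
        chain_order: list[str] = []
        grouped: dict[str, dict[tuple, list[AtomRecord]]] = {}
        for a in structure.model_atoms(imodel):
            if a.chain_id not in grouped:
                grouped[a.chain_id] = {}
                chain_order.append(a.chain_id)
            grouped[a.chain_id].setdefault(
                (a.residue_number, a.residue_name), []
            ).append(a)
        model = gemmi.Model(imodel)
        for cid in chain_order:
            chain = gemmi.Chain(cid)
            for (resnum, resname), recs in grouped[cid].items():
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                res.het_flag = "H" if recs[0].is_hetero else "A"
                for a in recs:
                    atom = gemmi.Atom()
                    atom.name = a.atom_name
                    atom.element = gemmi.Element(a.element)
                    atom.pos = gemmi.Position(*a.position)
                    atom.occ = a.occupancy
                    atom.altloc = a.altloc[:1] if a.altloc else "\0"
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(os.fspath(path))
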