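"""T / Rf / R conformational-state assignment for insulin monomers and
hexamers.

The three states differ in the fold of the B-chain N-terminus: in the
T-state B1-B6 is extended (followed by a B7-B10 type II' β-turn into the
invariant B9-B19 helix), in the R-state the B-chain helix runs from B1,
and in the frayed Rf-state the helix starts at B3 with B1-B2 departing
from the helical fold.  A hexamer label combines six monomer labels
(T6, T3Rf3, T3R3, R6, otherwise mixed).

The per-residue helicity criterion is a dihedral-window test on the
α-basin: φ in [-100°, -30°] and ψ in [-80°, -5°], with a helical run
requiring at least 4 consecutive helical residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .monomers import InsulinMonomer, backbone_dihedrals, identify_monomers

__all__ = [
    "StateAssignment",
    "classify_monomer_state",
    "classify_hexamer",
    "classify_structure",
    "is_helical",
]

PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)
MIN_RUN = 4

#: The helix whose start position defines the state must end at or past B17.
HELIX_END_MIN = 17
#: ... and state assignment needs B1-B19 backbone present.
B_SEGMENT_LAST = 19


@dataclass
class StateAssignment:
    monomer_states: list[str]  # each in {T, Rf, R, undetermined}
    hexamer_state: str  # T6 | T3Rf3 | T3R3 | R6 | mixed | undetermined
    helix_start: list[int | None]  # first residue of the defining B-helix


def is_helical(phi: float | None, psi: float | None) -> bool:
    """α-basin dihedral window test for a single residue."""
    if phi is None or psi is None:
        return False
    return PHI_WINDOW[0] <= phi <= PHI_WINDOW[1] and PSI_WINDOW[0] <= psi <= PSI_WINDOW[1]


def _helical_runs(helical: dict[int, bool]) -> list[tuple[int, int]]:
    """Maximal consecutive runs (start, end) of helical residues."""
    runs = []
    start = None
    prev = None
    for i in sorted(helical):
        if helical[i] and (prev == i - 1 and start is not None):
            prev = i
        elif helical[i]:
            if start is not None:
                runs.append((start, prev))
            start = prev = i
        else:
            if start is not None:
                runs.append((start, prev))
            start = prev = None
    if start is not None:
        runs.append((start, prev))
    return runs


def classify_monomer_state(monomer: InsulinMonomer) -> tuple[str, int | None]:
    """Assign T / Rf / R to one monomer from its B-chain dihedrals.

    Returns ``(state, helix_start)`` where ``helix_start`` is the first
    residue of the longest continuous helical run ending at or beyond
    B17.  Labels: R for a helix from B1/B2, Rf for B3/B4, T for a helix
    starting at B7 or later with a non-helical B1-B6, otherwise
    ``undetermined`` (including missing B1-B19 backbone).
    """
    if not monomer.has_backbone("B", 1, B_SEGMENT_LAST):
        return "undetermined", None
    torsions = backbone_dihedrals(monomer)["B"]
    helical = {i: is_helical(*torsions[i]) for i in sorted(torsions)}
    runs = [
        (start, end)
        for start, end in _helical_runs(helical)
        if end >= HELIX_END_MIN and end - start + 1 >= MIN_RUN
    ]
    if not runs:
        return "undetermined", None
    # longest qualifying run; ties resolved toward the earlier start
    start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    if start <= 2:
        return "R", start
    if start in (3, 4):
        return "Rf", start
    if start >= 7 and not any(helical.get(i, False) for i in range(1, 7)):
        return "T", start
    return "undetermined", start


def classify_hexamer(states: list[str]) -> str:
    """Combine six monomer labels into a hexamer label."""
    if len(states) != 6:
        raise ValueError(f"a hexamer has 6 monomers, got {len(states)} labels")
    if any(s == "undetermined" for s in states):
        return "undetermined"
    counts = Counter(states)
    if counts.get("T") == 6:
        return "T6"
    if counts.get("R") == 6:
        return "R6"
    if counts.get("T") == 3 and counts.get("R") == 3:
        return "T3R3"
    if counts.get("T") == 3 and counts.get("Rf") == 3:
        return "T3Rf3"
    return "mixed"


def classify_structure(structure, model: int = 1) -> StateAssignment:
    """Identify monomers and classify each plus, for six monomers, the
    hexamer; for other monomer counts the hexamer label is ``undetermined``."""
    monomers = identify_monomers(structure, model=model)
    labels: list[str] = []
    starts: list[int | None] = []
    for m in monomers:
        state, start = classify_monomer_state(m)
        labels.append(state)
        starts.append(start)
    hexamer = classify_hexamer(labels) if len(labels) == 6 else "undetermined"
    return StateAssignment(
        monomer_states=labels, hexamer_state=hexamer, helix_start=starts
    )
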