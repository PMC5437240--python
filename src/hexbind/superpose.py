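"""Rigid-body least-squares superposition (Kabsch) and plain r.m.s.d.

``superpose`` finds the proper rotation + translation that maps the second
coordinate set onto the first and reports the residual r.m.s.d.;
``rmsd_fixed`` evaluates r.m.s.d. in a fixed frame, as used for
per-ligand displacement series over the frames of a multi-model file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuperpositionResult", "superpose", "rmsd_fixed"]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # Å; maps b -> a as x @ R.T + t
    rmsd: float  # Å, after the fit
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def _check(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinate arrays")
    return a, b


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Proper rotations only (no reflection), via the SVD form of the Kabsch
    algorithm.  Requires >= 3 non-collinear points.
    """
    a, b = _check(coords_a, coords_b)
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    if np.linalg.matrix_rank(np.vstack([a0, b0]), tol=1e-9) < 2:
        raise ValueError("points are collinear; superposition is degenerate")
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ca - rot @ cb
    fitted = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def rmsd_fixed(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """r.m.s.d. between matched sets without fitting (fixed frame)."""
    a, b = _check(coords_a, coords_b)
    if a.shape[0] < 1:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
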