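"""Weighted Kabsch superposition of molecular geometries.

Reaction-path algebra (splines, tangents, perpendicular projectors)
presumes that consecutive frames live in a consistent body frame, i.e.
that rigid-body translation/rotation does not masquerade as internal
motion.  Multi-frame paths are therefore stored after sequential
mass-weighted Kabsch alignment to the first frame.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .geometry import Geometry


def _resolve_weights(g: Geometry, weights) -> np.ndarray:
    if weights is None or (isinstance(weights, str) and weights == "mass"):
        w = np.asarray(g.masses, dtype=float)
    elif isinstance(weights, str) and weights == "unit":
        w = np.ones(g.n_atoms)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (g.n_atoms,):
            raise ValueError("weights length must match number of atoms")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w


def rmsd(a: Geometry, b: Geometry, weights="mass") -> float:
    """Weighted root-mean-square deviation between two geometries (Å)."""
    if a.n_atoms != b.n_atoms:
        raise ValueError("geometries have different atom counts")
    w = _resolve_weights(a, weights)
    d2 = np.sum((a.coords - b.coords) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


def kabsch_align(mobile: Geometry, target: Geometry, weights="mass") -> Geometry:
    """Rigidly superimpose ``mobile`` onto ``target``.

    Returns a copy of ``mobile`` rotated and translated to minimize the
    weighted RMSD to ``target`` (weights default to atomic masses; pass
    ``"unit"`` for plain Cartesian RMSD).  Atom count and ordering must
    match.  Forces, when present, are rotated along with the coordinates.
    """
    if mobile.n_atoms != target.n_atoms:
        raise ValueError(
            f"atom count mismatch: {mobile.n_atoms} vs {target.n_atoms}"
        )
    if mobile.symbols != target.symbols:
        raise ValueError("element orderings differ between geometries")
    w = _resolve_weights(mobile, weights)
    wn = w / np.sum(w)
    cm = wn @ mobile.coords
    ct = wn @ target.coords
    P = mobile.coords - cm
    Q = target.coords - ct
    # covariance in the weighted metric; SVD with proper-rotation correction
    H = P.T @ (Q * wn[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    out = mobile.copy()
    out.coords = P @ R + ct
    if out.forces is not None:
        out.forces = out.forces @ R
    return out


def align_path(frames: Sequence[Geometry], weights="mass") -> list[Geometry]:
    """Sequentially Kabsch-align a multi-frame path to its first frame.

    Frame ``k`` is aligned to the already-aligned frame ``k − 1`` so that
    slowly rotating paths stay continuous.  Single-atom systems are
    returned unchanged (no rigid-body ambiguity worth removing for the
    model potentials this package uses them for).
    """
    frames = list(frames)
    if not frames or frames[0].n_atoms < 2:
        return [f.copy() for f in frames]
    out = [frames[0].copy()]
    for f in frames[1:]:
        out.append(kabsch_align(f, out[-1], weights=weights))
    return out
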