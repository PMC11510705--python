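"""Per-frame observables: backbone torsion ζ and terminal-base RMSD.

The torsion follows the IUPAC convention (cis = 0°, sign from the
two-argument arctangent form), output in (−180, 180].  RMSD is computed
over a named atom selection against a reference frame, optionally after
Kabsch superposition.  The default pipeline keeps superposition OFF: with
all but the terminal nucleotides harmonically restrained, the laboratory
frame is already a fixed frame of reference.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, SelectionError
from .io_formats import CoordinateFrameSet, TimeSeriesTable

#: An atom key: (chain id, residue index, atom name).
AtomKey = Tuple[str, int, str]

_COLLINEAR_TOL = 1e-10


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle (degrees, in (−180, 180]) of four points in Å.

    Uses φ = atan2(((n1×n2)·b2)/|b2|, n1·n2) with b_i the bond vectors and
    n1 = b1×b2, n2 = b2×b3.  Invariant under rigid motion; the sign flips
    under mirror reflection.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < _COLLINEAR_TOL:
        raise DegenerateGeometryError("central bond vector p3-p2 is zero")
    scale = max(np.linalg.norm(b1), 1.0) * max(norm_b2, 1.0)
    if np.linalg.norm(n1) < _COLLINEAR_TOL * scale:
        raise DegenerateGeometryError("points p1, p2, p3 are collinear")
    if np.linalg.norm(n2) < _COLLINEAR_TOL * max(norm_b2, 1.0) * max(np.linalg.norm(b3), 1.0):
        raise DegenerateGeometryError("points p2, p3, p4 are collinear")
    y = np.dot(np.cross(n1, n2), b2) / norm_b2
    x = np.dot(n1, n2)
    angle = np.degrees(np.arctan2(y, x))
    # atan2 returns [-180, 180]; fold the -180 boundary onto +180
    return float(angle if angle > -180.0 else 180.0)


@dataclass(frozen=True)
class AtomSelection:
    """Ordered atom keys resolving to coordinate indices in a frame set.

    Order is preserved — it matters for torsions.  Keys are written
    ``chain:residue:atom`` in configuration files, e.g. ``A:1:C3'``.
    """

    keys: Tuple[AtomKey, ...]

    @classmethod
    def from_strings(cls, specs: Sequence[str]) -> "AtomSelection":
        keys = []
        for spec in specs:
            parts = spec.split(":")
            if len(parts) != 3:
                raise SelectionError(f"bad selection {spec!r}, expected chain:residue:atom")
            keys.append((parts[0], int(parts[1]), parts[2]))
        return cls(tuple(keys))

    def resolve(self, frames: CoordinateFrameSet) -> np.ndarray:
        """Map every key to exactly one atom index; error otherwise."""
        indices = []
        for chain, res_id, name in self.keys:
            hits = np.flatnonzero(
                (frames.chain_ids == chain)
                & (frames.res_ids == res_id)
                & (frames.atom_names == name)
            )
            if len(hits) != 1:
                raise SelectionError(
                    f"selection {chain}:{res_id}:{name} resolved to {len(hits)} atoms"
                )
            indices.append(int(hits[0]))
        return np.asarray(indices, dtype=int)


def compute_rmsd(frame, reference, superpose: bool = False) -> float:
    """RMSD (Å) between matching coordinate arrays of shape (n, 3).

    With ``superpose`` the optimal-rotation (Kabsch) least-squares value is
    returned, which never exceeds the raw value.
    """
    a = np.asarray(frame, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise SelectionError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if len(a) < 1:
        raise SelectionError("need at least one selected atom")
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    if len(a) < 3:
        raise SelectionError("superposition needs at least 3 atoms")
    ca, cb = a - a.mean(axis=0), b - b.mean(axis=0)
    if np.linalg.matrix_rank(cb, tol=1e-9) < 2:
        raise SelectionError("superposition needs 3 non-collinear atoms")
    rot, _ = Rotation.align_vectors(cb, ca)
    return float(np.sqrt(np.mean(np.sum((rot.apply(ca) - cb) ** 2, axis=1))))


def observables_from_frames(
    frames: CoordinateFrameSet,
    torsion_selection: AtomSelection,
    rmsd_selection: AtomSelection,
    reference_index: int = 0,
    superpose: bool = False,
) -> TimeSeriesTable:
    """Compute the (time, RMSD, ζ) table the state classifier consumes.

    The reference structure defaults to the first frame.  The torsion
    selection must name exactly the four backbone atoms
    C3′(i), O3′(i), P(i+1), O5′(i+1) in order.
    """
    if len(torsion_selection.keys) != 4:
        raise SelectionError("torsion selection must contain exactly 4 atoms")
    if not 0 <= reference_index < frames.n_frames:
        raise SelectionError(
            f"reference index {reference_index} outside 0..{frames.n_frames - 1}"
        )
    tors_idx = torsion_selection.resolve(frames)
    rmsd_idx = rmsd_selection.resolve(frames)
    ref = frames.coords[reference_index][rmsd_idx]
    rmsd = np.empty(frames.n_frames)
    zeta = np.empty(frames.n_frames)
    for i in range(frames.n_frames):
        xyz = frames.coords[i]
        rmsd[i] = compute_rmsd(xyz[rmsd_idx], ref, superpose=superpose)
        zeta[i] = compute_dihedral(*xyz[tors_idx])
    return TimeSeriesTable.from_arrays(frames.times, rmsd, zeta, wrap=False)
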