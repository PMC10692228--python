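"""Vector geometry for covalent design.

Distances, bond angles, dihedral angles, internal-coordinate atom placement
(the NeRF construction used to grow side chains atom by atom), and optimal
rigid superposition (Kabsch) with RMSD.

Conventions
-----------
* All coordinates are Cartesian, in Angstrom, right-handed frame.
* Angles are degrees. Dihedral sign follows the IUPAC convention:
  looking down the p2->p3 axis, a clockwise rotation of the far bond
  relative to the near bond is positive; values lie in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GeometryError",
    "InternalCoordinate",
    "SuperpositionResult",
    "distance",
    "bond_angle",
    "dihedral_angle",
    "place_atom",
    "kabsch_superpose",
    "ca_distance",
]


class GeometryError(ValueError):
    """Degenerate geometric input (coincident or collinear reference points)."""


@dataclass(frozen=True)
class InternalCoordinate:
    """Internal-coordinate definition of one atom relative to three references.

    The atom is placed ``bond_length`` Angstrom from ``ref3``, forming
    ``bond_angle`` degrees with ref2-ref3 and torsion ``torsion`` degrees
    about the ref2-ref3 axis measured from ref1.
    """

    atom: str
    ref1: str
    ref2: str
    ref3: str
    bond_length: float
    bond_angle: float
    torsion: float

    def __post_init__(self) -> None:
        if not self.bond_length > 0:
            raise ValueError(f"bond_length must be > 0, got {self.bond_length}")
        if not 0 < self.bond_angle < 180:
            raise ValueError(f"bond_angle must be in (0, 180), got {self.bond_angle}")
        if not -180 < self.torsion <= 180:
            raise ValueError(f"torsion must be in (-180, 180], got {self.torsion}")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of a moving point set onto a fixed one.

    ``rotation`` is a proper 3x3 rotation (det = +1); applying
    ``x @ rotation.T + translation`` to the moving set minimises the RMSD,
    whose minimised value is stored in ``rmsd``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def distance(p1, p2) -> float:
    return float(np.linalg.norm(_as_vec(p1) - _as_vec(p2)))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees, in [0, 180]."""
    u = _as_vec(p1) - _as_vec(p2)
    v = _as_vec(p3) - _as_vec(p2)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("coincident points in angle computation")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Computed with the atan2 formulation, which is numerically stable near
    0 and 180. Raises :class:`GeometryError` when p1-p2-p3 or p2-p3-p4 are
    collinear (the torsion is then undefined).
    """
    p1, p2, p3, p4 = map(_as_vec, (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n2 = np.linalg.norm(b2)
    if n2 < 1e-12:
        raise GeometryError("coincident axis points p2, p3")
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    if np.linalg.norm(c1) < 1e-9 or np.linalg.norm(c2) < 1e-9:
        raise GeometryError("collinear reference points: torsion undefined")
    x = np.dot(c1, c2)
    y = np.dot(np.cross(c1, b2 / n2), c2)
    ang = float(np.degrees(np.arctan2(y, x)))
    # map -180 -> +180 so the range is (-180, 180]
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def _place(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Fast internal-coordinate placement; scalar math, no np.cross."""
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    n_bc = (bcx * bcx + bcy * bcy + bcz * bcz) ** 0.5
    n_ab = (abx * abx + aby * aby + abz * abz) ** 0.5
    if n_bc < 1e-12 or n_ab < 1e-12:
        raise GeometryError("coincident frame atoms")
    bcx, bcy, bcz = bcx / n_bc, bcy / n_bc, bcz / n_bc
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    n_n = (nx * nx + ny * ny + nz * nz) ** 0.5
    if n_n < 1e-9:
        raise GeometryError("collinear frame atoms a, b, c")
    nx, ny, nz = nx / n_n, ny / n_n, nz / n_n
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    theta = np.radians(bond_angle)
    phi = np.radians(torsion)
    u = -bond_length * np.cos(theta)
    v = bond_length * np.sin(theta) * np.cos(phi)
    w = -bond_length * np.sin(theta) * np.sin(phi)
    return np.array(
        [
            c[0] + u * bcx + v * mx + w * nx,
            c[1] + u * bcy + v * my + w * ny,
            c[2] + u * bcz + v * mz + w * nz,
        ]
    )


def place_atom(a, b, c, ic: InternalCoordinate) -> np.ndarray:
    """Place an atom from internal coordinates against frame atoms a, b, c.

    The returned point x satisfies |x - c| = bond_length,
    angle(b, c, x) = bond_angle and dihedral(a, b, c, x) = torsion.
    """
    a, b, c = map(_as_vec, (a, b, c))
    return _place(a, b, c, ic.bond_length, ic.bond_angle, ic.torsion)


def kabsch_superpose(moving, fixed, pairing=None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    ``pairing`` optionally maps moving indices onto fixed indices
    (``pairing[i]`` pairs ``moving[i]`` with ``fixed[pairing[i]]``).
    Only proper rotations are considered.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if pairing is not None:
        fixed = fixed[np.asarray(pairing, dtype=int)]
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape != fixed.shape:
        raise ValueError("moving and fixed must be paired (n, 3) arrays")
    if len(moving) < 3:
        raise GeometryError("need at least 3 paired points for superposition")
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    rot, rssd = Rotation.align_vectors(fixed - mu_f, moving - mu_m)
    matrix = rot.as_matrix()
    translation = mu_f - matrix @ mu_m
    rmsd = float(rssd / np.sqrt(len(moving)))
    return SuperpositionResult(rotation=matrix, translation=translation, rmsd=rmsd)


def ca_distance(res_a, res_b) -> float:
    """Calpha-Calpha distance in Angstrom between two residue records."""
    from .structure import MissingAtomError  # cyclic at module load otherwise

    pos = []
    for res in (res_a, res_b):
        atom = res.get_atom("CA")
        if atom is None:
            raise MissingAtomError(
                f"residue {res.name} {res.chain_id}{res.seq_number} has no CA atom"
            )
        pos.append(atom.position)
    return distance(pos[0], pos[1])
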