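"""Numeric kernel: least-square planes, rigid superposition, backbone
dihedrals, Ramachandran quadrants and solvent-accessible surface area.

All coordinates are in Å and all angles in degrees. The least-square
(best-fit) plane is the total-least-squares plane: it minimises the sum of
squared *orthogonal* distances to the points, which is the plane used both
for deciding which side of an interface a partner chain lies on and for
measuring interface planarity.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DegenerateGeometryError",
    "Plane",
    "DihedralPair",
    "SuperpositionResult",
    "fit_lsq_plane",
    "signed_side",
    "kabsch_superpose",
    "dihedral_angle",
    "bond_angle",
    "backbone_dihedrals",
    "n_ca_c_angle",
    "delta_phi_psi",
    "wrap_degrees",
    "quadrant_of",
    "sasa",
    "load_vdw_radii",
    "sphere_points",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric primitive is undefined for its input
    (fewer than three points, collinear points, ...)."""


@dataclass(frozen=True)
class Plane:
    """Plane {p : normal·p + offset = 0} with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,) or not np.isfinite(n).all():
            raise ValueError("plane normal must be a finite 3-vector")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must have unit length")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, point: Sequence[float]) -> float:
        return float(self.normal @ np.asarray(point, dtype=float) + self.offset)


@dataclass(frozen=True)
class DihedralPair:
    """Backbone (φ, ψ) of one residue, in degrees in (−180, 180].

    Either angle is ``None`` when the defining atoms are absent (chain
    termini, missing density or a chain break).
    """

    phi: float | None
    psi: float | None

    @property
    def defined(self) -> bool:
        return self.phi is not None and self.psi is not None


@dataclass
class SuperpositionResult:
    """Rigid transform ``x ↦ rotation @ x + translation`` of the moving set
    onto the fixed set, with the RMSD over the pairing used to derive it."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    equivalences: list = field(default_factory=list)

    def transform(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def fit_lsq_plane(points: Iterable[Sequence[float]]) -> Plane:
    """Total-least-squares plane through ``points``.

    The normal is the singular vector of the centred coordinate matrix with
    the smallest singular value; its sign is fixed so that the first nonzero
    component is positive. Collinear input (no unique plane) raises
    :class:`DegenerateGeometryError`.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    scale = max(s[0], 1.0)
    if s[1] <= 1e-8 * scale:
        raise DegenerateGeometryError("points are collinear; plane is not unique")
    normal = vt[2]
    for component in normal:
        if abs(component) > 1e-12:
            if component < 0:
                normal = -normal
            break
    normal = normal / np.linalg.norm(normal)
    return Plane(normal=normal, offset=float(-normal @ centroid))


def signed_side(plane: Plane, point: Sequence[float], epsilon: float = 1e-6) -> int:
    """Which side of ``plane`` the point lies on: +1, −1, or 0 within
    ``epsilon`` Å of the plane."""
    d = plane.signed_distance(point)
    if abs(d) <= epsilon:
        return 0
    return 1 if d > 0 else -1


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of paired point sets.

    Returns the proper rotation (det = +1) and translation minimising the
    RMSD of ``rotation @ moving + translation`` against ``fixed``.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape:
        raise ValueError(f"paired point sets differ in shape: {mov.shape} vs {fix.shape}")
    if mov.ndim != 2 or mov.shape[1] != 3 or mov.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 paired points")
    mc, fc = mov.mean(axis=0), fix.mean(axis=0)
    h = (mov - mc).T @ (fix - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = fc - rot @ mc
    diff = mov @ rot.T + trans - fix
    rmsd = float(np.sqrt((diff**2).sum() / mov.shape[0]))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = n1 @ n2, m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 at the central atom, in degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1, v2 = p1 - p2, p3 - p2
    cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


_CHAIN_BREAK_N_C = 2.5  # Å; peptide C(i-1)–N(i) beyond this is a break


def backbone_dihedrals(residues: Sequence) -> list[DihedralPair]:
    """Per-residue (φ, ψ) for an ordered residue collection.

    φ_i is C(i−1)–N(i)–CA(i)–C(i) and ψ_i is N(i)–CA(i)–C(i)–N(i+1).
    Angles are undefined at termini, wherever a backbone atom is missing,
    and across chain breaks (C(i−1)–N(i) distance > 2.5 Å).
    """
    coords = []
    for res in residues:
        entry = {}
        for name in ("N", "CA", "C"):
            atom = res.atom(name)
            entry[name] = None if atom is None else atom.coord
        coords.append(entry)

    def _bonded(c_prev, n_next) -> bool:
        return (
            c_prev is not None
            and n_next is not None
            and float(np.linalg.norm(c_prev - n_next)) <= _CHAIN_BREAK_N_C
        )

    out: list[DihedralPair] = []
    for i, cur in enumerate(coords):
        phi = psi = None
        if cur["N"] is not None and cur["CA"] is not None and cur["C"] is not None:
            if i > 0 and _bonded(coords[i - 1]["C"], cur["N"]):
                phi = dihedral_angle(coords[i - 1]["C"], cur["N"], cur["CA"], cur["C"])
            if i + 1 < len(coords) and _bonded(cur["C"], coords[i + 1]["N"]):
                psi = dihedral_angle(cur["N"], cur["CA"], cur["C"], coords[i + 1]["N"])
        out.append(DihedralPair(phi=phi, psi=psi))
    return out


def n_ca_c_angle(residue) -> float | None:
    """Backbone N–Cα–C′ bond angle of one residue (degrees), or None."""
    atoms = [residue.atom(n) for n in ("N", "CA", "C")]
    if any(a is None for a in atoms):
        return None
    return bond_angle(atoms[0].coord, atoms[1].coord, atoms[2].coord)


def wrap_degrees(delta: float) -> float:
    """Map an angle difference into (−180, 180]."""
    wrapped = (delta + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def delta_phi_psi(a: DihedralPair, b: DihedralPair) -> float | None:
    """Conformational difference Δ(φ,ψ) between two residues in degrees:
    the Euclidean norm of the wrapped (Δφ, Δψ) vector.

    Undefined (None) if either pair is undefined; an undefined Δ is never
    compared against the hinge-extension threshold.
    """
    if not (a.defined and b.defined):
        return None
    dphi = wrap_degrees(a.phi - b.phi)
    dpsi = wrap_degrees(a.psi - b.psi)
    return float(np.hypot(dphi, dpsi))


def quadrant_of(d: DihedralPair, tie_break: str = "q1") -> str:
    """Ramachandran quadrant of a (φ, ψ) pair.

    Q1: φ<0, ψ>0 (upper left, extended/β);  Q2: φ>0, ψ>0 (α-L region);
    Q3: φ>0, ψ<0;  Q4: φ<0, ψ<0 (lower left, α-R).  Boundary values
    (φ or ψ exactly 0 or ±180) are assigned with a negative-φ / positive-ψ
    preference by default (``tie_break='q1'``).
    """
    if not d.defined:
        raise ValueError("quadrant undefined for incomplete (phi, psi) pair")
    if tie_break != "q1":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    phi, psi = d.phi, d.psi
    # ±180 is the same boundary as ∓180; fold onto the negative-φ preference
    phi_neg = phi < 0 or abs(phi) in (0.0, 180.0)
    psi_pos = psi > 0 or abs(psi) in (0.0, 180.0)
    if phi_neg:
        return "Q1" if psi_pos else "Q4"
    return "Q2" if psi_pos else "Q3"


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

_DEFAULT_RADIUS = 1.70  # Å, carbon-like fallback
_radii_cache: dict[str, float] | None = None


def load_vdw_radii() -> Mapping[str, float]:
    """Packaged van der Waals radii (Bondi-style), element symbol → Å."""
    global _radii_cache
    if _radii_cache is None:
        table = {}
        text = (
            importlib.resources.files("hide.data")
            .joinpath("vdw_radii.csv")
            .read_text()
        )
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            element, radius = line.split(",")
            table[element.strip().upper()] = float(radius)
        _radii_cache = table
    return _radii_cache


def vdw_radius(element: str) -> float:
    return load_vdw_radii().get(element.upper(), _DEFAULT_RADIUS)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral
    lattice); fixed for a given ``n`` so SASA is reproducible."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    residues: Sequence,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> dict:
    """Per-residue solvent-accessible surface area (Å²) by the
    Shrake–Rupley method.

    ``residues`` is any ordered collection of Residue objects; the set
    itself defines the occlusion context. Hydrogens, when present, are
    ignored. Returns ``{residue.key: area}``.
    """
    res_list = list(residues)
    atom_coords, atom_radii, atom_res = [], [], []
    for ridx, res in enumerate(res_list):
        for atom in res.atoms:
            if atom.element.upper() == "H":
                continue
            atom_coords.append(atom.coord)
            r = (radii or load_vdw_radii()).get(atom.element.upper(), _DEFAULT_RADIUS)
            atom_radii.append(r + probe)
            atom_res.append(ridx)
    if not atom_coords:
        raise ValueError("SASA of an empty atom set is undefined")
    coords = np.asarray(atom_coords, dtype=float)
    radii_arr = np.asarray(atom_radii, dtype=float)
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * radii_arr.max()
    areas = np.zeros(len(res_list))
    for i in range(len(coords)):
        shell = coords[i] + radii_arr[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            # coincident duplicate atoms (e.g. unresolved altlocs): only the
            # first contributes area, so the union equals a single sphere
            if np.linalg.norm(coords[i] - coords[j]) < 1e-6:
                if j < i:
                    exposed[:] = False
                    break
                continue
            d = np.linalg.norm(shell - coords[j], axis=1)
            exposed &= d >= radii_arr[j]
            if not exposed.any():
                break
        frac = exposed.sum() / n_points
        areas[atom_res[i]] += frac * 4.0 * np.pi * radii_arr[i] ** 2
    return {res_list[ridx].key: float(areas[ridx]) for ridx in range(len(res_list))}
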