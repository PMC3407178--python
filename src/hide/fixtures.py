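"""Synthetic structures with known ground truth.

Everything here is generated programmatically: a poly-backbone protomer is
built from ideal internal coordinates (fixed bond lengths and angles,
user-specified torsions), and oligomers are assembled from rigid copies of
it. Two conformers of the same protomer are produced:

* the **open** form (as found in a swapped dimer): body helix, extended
  hinge in the upper-left (Q1) Ramachandran quadrant, and the swap segment
  continuing as an extended strand, laterally offset from the body axis;
* the **closed** form (the monomer): identical body and swap torsions but
  the hinge switched toward a reverse turn (Q4), folding the swap segment
  back against the body.

A swapped dimer is the open protomer plus its two-fold image about the
lateral-offset axis, which docks each chain's swap segment against the far
face of the partner's body — so the partner chain genuinely crosses the
least-square plane of the interface. A side-by-side dimer is two closed
protomers related by a pure translation. Ground-truth labels (swap segment,
hinge interval, expected crossing block) are returned with every oligomer
and are what the test-suite asserts against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import Atom, Chain, Residue, Structure

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "build_chain",
    "build_protomer",
    "build_monomer_homologue",
    "build_swapped_dimer",
    "build_side_by_side_dimer",
    "build_trimer",
    "make_residue",
    "HELIX", "STRAND", "TURN",
]

# ideal backbone internal coordinates (Engh–Huber-like)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5
_OMEGA = 180.0
_IMPROPER_N_C_CA_CB = 122.7  # places CB for an L-amino acid

HELIX = (-57.0, -47.0)
STRAND = (-130.0, 150.0)   # extended, Q1
TURN = (-75.0, -35.0)      # helical reverse turn, Q4

_AA20 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic protomer family.

    ``swap_segment`` and ``hinge_interval`` are inclusive 1-based residue
    number ranges; the hinge must immediately precede the swap segment and
    both must lie inside the protomer. ``orientation_change`` (degrees,
    0 < oc ≤ 90) interpolates the closed-form hinge torsions between the
    open extended recipe (0) and a full reverse turn (90): it is the knob
    controlling how far the swap segment reorients between the two forms.
    ``geometry_noise_sigma`` is an isotropic Gaussian jitter (Å) applied to
    every atom. A fixed seed yields bit-identical output.
    """

    protomer_length: int = 42
    swap_segment: tuple[int, int] = (28, 42)
    hinge_interval: tuple[int, int] = (25, 27)
    geometry_noise_sigma: float = 0.05
    orientation_change: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        h1, h2 = self.hinge_interval
        s1, s2 = self.swap_segment
        if not (1 <= h1 <= h2 < s1 <= s2 <= self.protomer_length):
            raise ValueError("require 1 ≤ hinge ≤ swap ≤ protomer_length, hinge before swap")
        if s1 != h2 + 1:
            raise ValueError("swap segment must start immediately after the hinge")
        if not (0.0 < self.orientation_change <= 90.0):
            raise ValueError("orientation_change must be in (0, 90] degrees")


@dataclass
class GroundTruth:
    form: str
    chain_ids: list[str]
    swap_segment: tuple[int, int] | None = None
    hinge_interval: tuple[int, int] | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: position d with |cd| = bond,
    angle(b,c,d) = angle and torsion(a,b,c,d) = torsion."""
    theta, chi = np.radians(angle_deg), np.radians(-torsion_deg)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def build_chain(
    torsions: Sequence[tuple[float, float]],
    sequence: Sequence[str],
    chain_id: str = "A",
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    first_residue_number: int = 1,
) -> Chain:
    """Backbone chain (N, CA, C, O and CB for non-Gly) from per-residue
    (φ, ψ) torsions; ω is ideal trans throughout.

    φ of the first residue is not realisable (no preceding C) and is
    ignored; ψ of the last residue only orients the terminal carbonyl.
    """
    n = len(torsions)
    if len(sequence) != n:
        raise ValueError("torsions and sequence lengths differ")
    if rng is None:
        rng = np.random.default_rng(0)

    ncac = np.zeros((n, 3, 3))
    ncac[0, 0] = (0.0, 0.0, 0.0)
    ncac[0, 1] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    ncac[0, 2] = ncac[0, 1] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        phi = torsions[i][0]
        psi_prev = torsions[i - 1][1]
        ncac[i, 0] = _place(ncac[i - 1, 0], ncac[i - 1, 1], ncac[i - 1, 2],
                            _B_C_N, _A_CA_C_N, psi_prev)
        ncac[i, 1] = _place(ncac[i - 1, 1], ncac[i - 1, 2], ncac[i, 0],
                            _B_N_CA, _A_C_N_CA, _OMEGA)
        ncac[i, 2] = _place(ncac[i - 1, 2], ncac[i, 0], ncac[i, 1],
                            _B_CA_C, _A_N_CA_C, phi)

    residues = []
    for i, aa in enumerate(sequence):
        atoms = [
            Atom("N", "N", ncac[i, 0].copy()),
            Atom("CA", "C", ncac[i, 1].copy()),
            Atom("C", "C", ncac[i, 2].copy()),
        ]
        o = _place(ncac[i, 0], ncac[i, 1], ncac[i, 2],
                   _B_C_O, _A_CA_C_O, torsions[i][1] - 180.0)
        atoms.append(Atom("O", "O", o))
        if aa != "GLY":
            cb = _place(ncac[i, 0], ncac[i, 2], ncac[i, 1],
                        _B_CA_CB, _A_N_CA_CB, _IMPROPER_N_C_CA_CB)
            atoms.append(Atom("CB", "C", cb))
        residues.append(
            Residue(chain_id=chain_id, seq_number=first_residue_number + i,
                    insertion_code="", aa_type=aa, atoms=atoms)
        )
    if noise_sigma > 0:
        for res in residues:
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(0.0, noise_sigma, 3)
    return Chain(chain_id=chain_id, residues=residues)


def _default_sequence(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    # glycine and proline excluded: torsions are imposed anyway and every
    # residue should carry a CB for the contact-based analyses
    pool = [aa for aa in _AA20 if aa not in ("GLY", "PRO")]
    return [pool[i] for i in rng.integers(0, len(pool), spec.protomer_length)]


# Closed-form hinge torsion recipes per hinge length, found once by a grid
# search for maximal fold-back of the swap tail against the body (the tail
# axis ends up > 150° from the body axis at a 6–11 Å lateral offset). All
# entries sit in the lower-left (Q4) Ramachandran quadrant.
_CLOSED_HINGE: dict[int, list[tuple[float, float]]] = {
    1: [(-100.0, -100.0)],
    2: [(-100.0, -100.0)] * 2,
    3: [(-55.0, -130.0)] * 3,
    4: [(-10.0, -145.0)] * 4,
    5: [(-175.0, -40.0)] + [(-85.0, -145.0)] * 4,
}


def _closed_recipe(h: int) -> list[tuple[float, float]]:
    if h in _CLOSED_HINGE:
        return list(_CLOSED_HINGE[h])
    return [(-175.0, -40.0)] * (h - 4) + [(-85.0, -145.0)] * 4


def _hinge_at(recipe, t: float):
    from .geometry import wrap_degrees

    return [
        (
            wrap_degrees(STRAND[0] + t * wrap_degrees(phi - STRAND[0])),
            wrap_degrees(STRAND[1] + t * wrap_degrees(psi - STRAND[1])),
        )
        for phi, psi in recipe
    ]


def _assemble(spec: FixtureSpec, hinge) -> list[tuple[float, float]]:
    h1, h2 = spec.hinge_interval
    out = []
    for num in range(1, spec.protomer_length + 1):
        if num < h1:
            out.append(HELIX)
        elif num <= h2:
            out.append(hinge[num - h1])
        else:
            out.append(STRAND)
    return out


def _tail_axis(torsions, spec: FixtureSpec) -> np.ndarray:
    chain = build_chain(torsions, ["ALA"] * spec.protomer_length)
    s1, s2 = spec.swap_segment
    tail = np.array([r.atom("CA").coord for r in chain.residues
                     if s1 <= r.seq_number <= s2])
    _, _, vt = np.linalg.svd(tail - tail.mean(axis=0), full_matrices=False)
    axis = vt[0]
    return axis if axis @ (tail[-1] - tail[0]) > 0 else -axis


_t_cache: dict[tuple, float] = {}


def _solve_closed_t(spec: FixtureSpec) -> float:
    """Interpolation factor t so the measured reorientation of the swap
    tail between open and closed conformers equals ``orientation_change``
    degrees (consecutive hinge torsion changes can partly cancel, so the
    torsion offset itself is not a faithful angle).

    Bond geometry is deterministic, so the solution is cached per
    (length, hinge, swap) layout."""
    key = (spec.protomer_length, spec.hinge_interval, spec.swap_segment,
           round(spec.orientation_change, 3))
    if key in _t_cache:
        return _t_cache[key]
    recipe = _closed_recipe(spec.hinge_interval[1] - spec.hinge_interval[0] + 1)
    open_axis = _tail_axis(_assemble(spec, _hinge_at(recipe, 0.0)), spec)

    def angle(t: float) -> float:
        axis = _tail_axis(_assemble(spec, _hinge_at(recipe, t)), spec)
        return float(np.degrees(np.arccos(np.clip(open_axis @ axis, -1.0, 1.0))))

    grid = np.linspace(0.02, 1.0, 50)
    angles = np.array([angle(t) for t in grid])
    best = int(np.argmin(np.abs(angles - spec.orientation_change)))
    t = float(grid[best])
    # contract: every hinge residue's (φ,ψ) must differ between the two
    # conformers by clearly more than the 20° detection threshold — the
    # 0.05 Å coordinate jitter translates to ~7° of Δ(φ,ψ) noise, so the
    # design point is set ≈3σ above the threshold. The requested
    # reorientation is honoured only down to this floor.
    from .geometry import wrap_degrees

    per_residue = [
        np.hypot(wrap_degrees(phi - STRAND[0]), wrap_degrees(psi - STRAND[1]))
        for phi, psi in recipe
    ]
    t_floor = min(1.0, 40.0 / min(per_residue))
    t = max(t, t_floor)
    _t_cache[key] = t
    return t


def _torsions(spec: FixtureSpec, conformer: str) -> list[tuple[float, float]]:
    h1, h2 = spec.hinge_interval
    recipe = _closed_recipe(h2 - h1 + 1)
    if conformer == "open":
        hinge = [STRAND] * (h2 - h1 + 1)
    elif conformer == "closed":
        hinge = _hinge_at(recipe, _solve_closed_t(spec))
    else:
        raise ValueError(f"unknown conformer {conformer!r}")
    return _assemble(spec, hinge)


def build_protomer(
    spec: FixtureSpec,
    conformer: str = "open",
    chain_id: str = "A",
    sequence: Sequence[str] | None = None,
) -> Structure:
    """Single-chain protomer in the open or closed conformation."""
    rng = np.random.default_rng(spec.seed)
    seq = list(sequence) if sequence is not None else _default_sequence(spec, rng)
    chain = build_chain(_torsions(spec, conformer), seq, chain_id=chain_id,
                        noise_sigma=spec.geometry_noise_sigma, rng=rng)
    return Structure(pdb_id=f"fx{conformer[0]}{spec.seed % 10000:04d}", chains=[chain])


def build_monomer_homologue(spec: FixtureSpec, mutate: float = 0.0) -> Structure:
    """Closed-form (non-swapped) protomer, optionally with a ``mutate``
    fraction of positions substituted — the homologue input of the hinge
    search."""
    rng = np.random.default_rng(spec.seed)
    seq = _default_sequence(spec, rng)
    if mutate > 0:
        mrng = np.random.default_rng(spec.seed + 7919)
        for i in range(len(seq)):
            if mrng.random() < mutate:
                options = [aa for aa in _AA20 if aa not in ("GLY", "PRO", seq[i])]
                seq[i] = options[mrng.integers(0, len(options))]
    chain = build_chain(_torsions(spec, "closed"), seq, chain_id="A",
                        noise_sigma=spec.geometry_noise_sigma,
                        rng=np.random.default_rng(spec.seed))
    return Structure(pdb_id=f"fxm{spec.seed % 1000:03d}", chains=[chain])


# ---------------------------------------------------------------------------
# rigid assembly
# ---------------------------------------------------------------------------

def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _transform_chain(chain: Chain, rot: np.ndarray, trans: np.ndarray,
                     new_id: str) -> Chain:
    residues = []
    for res in chain.residues:
        atoms = [Atom(a.name, a.element, rot @ a.coord + trans, a.occupancy)
                 for a in res.atoms]
        residues.append(Residue(new_id, res.seq_number, res.insertion_code,
                                res.aa_type, atoms, res.standard))
    return Chain(chain_id=new_id, residues=residues)


def _segment_frames(chain: Chain, spec: FixtureSpec):
    """Body axis (first principal direction, oriented N→C) and the
    body/swap centroids of one protomer chain."""
    h1, _ = spec.hinge_interval
    s1, s2 = spec.swap_segment
    ca = {r.seq_number: r.atom("CA").coord for r in chain.residues if r.atom("CA")}
    body = np.array([ca[n] for n in range(1, h1) if n in ca])
    swap = np.array([ca[n] for n in range(s1, s2 + 1) if n in ca])
    c_b, c_s = body.mean(axis=0), swap.mean(axis=0)
    centred = body - c_b
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    u = vt[0]
    if u @ (body[-1] - body[0]) < 0:
        u = -u
    return u, c_b, c_s


def build_swapped_dimer(
    spec: FixtureSpec,
    placement_noise_deg: float = 0.0,
    dock_distance: float = 9.0,
) -> tuple[Structure, GroundTruth]:
    """Reciprocally exchanged dimer with known swap segment and hinge.

    Chain B is the two-fold image of the open protomer about the axis along
    the lateral body→swap offset: B's swap strand runs along the far face
    of A's body (and vice versa), so each chain crosses the least-square
    plane fitted through the partner's interface residues, with the
    crossing block equal to the swap segment (± a hinge residue).
    """
    mono = build_protomer(spec, conformer="open", chain_id="A")
    chain_a = mono.chains[0]
    u, c_b, c_s = _segment_frames(chain_a, spec)
    delta = c_s - c_b
    length = np.linalg.norm(delta)
    d_hat = delta / length
    v = delta - (delta @ u) * u
    if np.linalg.norm(v) < 1.0:
        raise ValueError("degenerate fixture: swap segment is collinear with the body axis")
    # two-fold axis n̂ with Δ·n̂ = −dock: the image of the body centroid then
    # lands at dock Å beside the swap centroid, and the image of the swap
    # centroid at dock Å on the *opposite* face of the body — the partner
    # chain must cross the interface plane. The axis is tilted out of the
    # body/swap plane so the two chains pack without threading each other.
    q = np.cross(d_hat, v / np.linalg.norm(v))
    q /= np.linalg.norm(q)
    beta = dock_distance / length
    n_hat = np.sqrt(max(0.0, 1.0 - beta**2)) * q - beta * d_hat
    rot = _rotation_about(n_hat, 180.0)
    trans = (c_s + dock_distance * n_hat) - rot @ c_b
    if placement_noise_deg > 0:
        prng = np.random.default_rng(spec.seed + 104729)
        axis = prng.normal(size=3)
        wobble = _rotation_about(axis, prng.uniform(-placement_noise_deg,
                                                    placement_noise_deg))
        # wobble about the placed body centroid so contacts are preserved
        centre = rot @ c_b + trans
        rot = wobble @ rot
        trans = centre - rot @ c_b
    chain_b = _transform_chain(chain_a, rot, trans, "B")
    structure = Structure(pdb_id=f"fxd{spec.seed % 1000:03d}",
                          chains=[chain_a, chain_b])
    truth = GroundTruth(form="swapped-dimer", chain_ids=["A", "B"],
                        swap_segment=spec.swap_segment,
                        hinge_interval=spec.hinge_interval)
    return structure, truth


def _min_interchain_distance(a: Chain, b: Chain) -> float:
    from scipy.spatial import cKDTree

    pa = np.array([at.coord for r in a.residues for at in r.heavy_atoms()])
    pb = np.array([at.coord for r in b.residues for at in r.heavy_atoms()])
    return float(cKDTree(pa).query(pb)[0].min())


def build_side_by_side_dimer(
    spec: FixtureSpec,
    placement_noise_deg: float = 0.0,
    contact_distance: float = 4.5,
    separation: float | None = None,
) -> tuple[Structure, GroundTruth]:
    """Two closed (unexchanged) protomers related by a pure translation,
    touching at ``contact_distance`` Å; ``separation`` overrides the
    translation magnitude (100 Å gives the no-interface case)."""
    mono = build_protomer(spec, conformer="closed", chain_id="A")
    chain_a = mono.chains[0]
    # dock face-on, along the flattest principal direction of the protomer,
    # so the translated copy lies squarely on one side of any interface
    # plane; the hinge loop bulges out of the slab, so dock on the face it
    # points away from
    ca = chain_a.ca_coords()
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid, full_matrices=False)
    w = vt[2]
    h1, h2 = spec.hinge_interval
    loop = np.array([r.atom("CA").coord for r in chain_a.residues
                     if h1 - 2 <= r.seq_number <= h2 + 2 and r.atom("CA")])
    if (loop.mean(axis=0) - centroid) @ w > 0:
        w = -w
    if placement_noise_deg > 0:
        prng = np.random.default_rng(spec.seed + 15485863)
        wobble = _rotation_about(prng.normal(size=3),
                                 prng.uniform(-placement_noise_deg, placement_noise_deg))
        w = wobble @ w
    if separation is None:
        # two passes home in on the requested surface-to-surface gap
        t = 12.0
        for _ in range(3):
            probe = _transform_chain(chain_a, np.eye(3), t * w, "B")
            gap = _min_interchain_distance(chain_a, probe)
            t += contact_distance - gap
    else:
        t = separation
    chain_b = _transform_chain(chain_a, np.eye(3), t * w, "B")
    structure = Structure(pdb_id=f"fxs{spec.seed % 1000:03d}",
                          chains=[chain_a, chain_b])
    truth = GroundTruth(form="side-by-side-dimer", chain_ids=["A", "B"],
                        swap_segment=None, hinge_interval=None)
    return structure, truth


def build_trimer(spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    """Swapped A–B pair plus a third, side-by-side chain C docked onto A:
    exactly one chain pair is exchanged."""
    dimer, truth = build_swapped_dimer(spec)
    chain_a = dimer.chains[0]
    closed = build_protomer(spec, conformer="closed").chains[0]
    # the +n̂ face of A's body (opposite B's docked swap) is free; present
    # the *flat face* of the closed partner to it so the contact patch is
    # two-dimensional and its interface plane well conditioned
    u, c_b, c_s = _segment_frames(chain_a, spec)
    delta = c_s - c_b
    length = np.linalg.norm(delta)
    d_hat = delta / length
    v = delta - (delta @ u) * u
    q = np.cross(d_hat, v / np.linalg.norm(v))
    q /= np.linalg.norm(q)
    beta = 9.0 / length
    n_hat = np.sqrt(max(0.0, 1.0 - beta**2)) * q - beta * d_hat

    ca_c = closed.ca_coords()
    centroid_c = ca_c.mean(axis=0)
    _, _, vt = np.linalg.svd(ca_c - centroid_c, full_matrices=False)
    e1, e3 = vt[0], vt[2]
    frame_from = np.column_stack([e1, np.cross(e3, e1), e3])
    u_perp = u - (u @ n_hat) * n_hat
    u_perp /= np.linalg.norm(u_perp)
    frame_to = np.column_stack([u_perp, np.cross(n_hat, u_perp), n_hat])
    rot_c = frame_to @ frame_from.T
    base = rot_c @ (np.eye(3) @ -centroid_c) + c_b
    aligned = _transform_chain(closed, rot_c, base, "C")
    t = 12.0
    for _ in range(4):
        probe = _transform_chain(aligned, np.eye(3), t * n_hat, "C")
        gap = _min_interchain_distance(chain_a, probe)
        t += 4.5 - gap
    chain_c = _transform_chain(aligned, np.eye(3), t * n_hat, "C")
    structure = Structure(pdb_id=f"fxt{spec.seed % 1000:03d}",
                          chains=[dimer.chains[0], dimer.chains[1], chain_c])
    truth = GroundTruth(form="trimer-one-swapped-pair", chain_ids=["A", "B", "C"],
                        swap_segment=spec.swap_segment,
                        hinge_interval=spec.hinge_interval)
    return structure, truth


def make_residue(
    chain_id: str, seq_number: int, aa_type: str,
    atoms: dict[str, tuple[float, float, float]],
    elements: dict[str, str] | None = None,
) -> Residue:
    """Hand-built residue for micro-fixtures (feature-count tests):
    ``atoms`` maps atom name → coordinate; elements default to the first
    letter of the atom name."""
    built = []
    for name, coord in atoms.items():
        element = (elements or {}).get(name) or name.strip("0123456789")[0]
        built.append(Atom(name, element, np.asarray(coord, dtype=float)))
    return Residue(chain_id=chain_id, seq_number=seq_number, insertion_code="",
                   aa_type=aa_type, atoms=built)
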