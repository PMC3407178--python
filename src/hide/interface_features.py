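"""Structural features of oligomer interfaces, and the swapped-domain
(DSI) versus non-swapped-domain (NDSI) comparison.

An interface residue is one whose solvent accessibility drops by at least
1 Å² on complex formation. Nine features are counted per interface —
disulfides, hydrophobic contacts, short contacts, salt bridges, hydrogen
bonds, van der Waals contacts, structural segments, protrusion index and
planarity — normalised by interface area, and compared across paired
DSI/NDSI observations with a paired t-test.

Counting levels follow the per-residue framing of the source definitions:
residue pairs for disulfide, hydrophobic, salt-bridge and short contacts;
atom pairs for van der Waals contacts and hydrogen bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import bond_angle, fit_lsq_plane, load_vdw_radii, sasa
from .structure_io import Chain, Residue, Structure

__all__ = [
    "InterfaceDefinition",
    "InterfacePair",
    "InterfaceFeatureSet",
    "define_interface",
    "disulfide_bonds",
    "hydrophobic_contacts",
    "short_contacts",
    "salt_bridges",
    "hydrogen_bonds",
    "vdw_contacts",
    "electrostatic_interactions",
    "structural_segments",
    "protrusion_index",
    "planarity",
    "compute_feature_set",
    "split_dsi_ndsi",
    "compare_dsi_ndsi",
    "HYDROPHOBIC_RESIDUES",
]

#: The hydrophobic residue set used for Cβ–Cβ contact counting (Trp is
#: included as the intended member of the aromatic trio).
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "LEU", "ILE", "VAL", "TRP", "TYR", "PHE"})

_POSITIVE_SIDECHAIN_N = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),  # protonatable, counted as positive
}
_NEGATIVE_SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class InterfaceDefinition:
    """Interface residues of one side of a chain pair, by ΔSASA."""

    chain_id: str
    residues: list  # residue keys with ΔSASA ≥ threshold
    dsasa: dict     # residue key → ΔSASA (Å²), interface residues only
    area: float     # Å², sum of ΔSASA over this side's interface residues
    side_label: str = ""


@dataclass
class InterfacePair:
    """The two residue sets (as Residue objects) forming one interface."""

    residues_a: list[Residue]
    residues_b: list[Residue]

    def __post_init__(self) -> None:
        self.residues_a = list(self.residues_a)
        self.residues_b = list(self.residues_b)


def define_interface(
    structure: Structure,
    chain_pair: tuple[str, str],
    dsasa_threshold: float = 1.0,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[InterfaceDefinition, InterfaceDefinition]:
    """Interface residues of both sides of ``chain_pair``: per-residue
    ΔSASA = SASA(isolated chain) − SASA(in the two-chain complex), kept if
    ≥ ``dsasa_threshold`` Å²."""
    chain_a = structure.chain(chain_pair[0])
    chain_b = structure.chain(chain_pair[1])
    together = list(chain_a.residues) + list(chain_b.residues)
    complexed = sasa(together, probe=probe, n_points=n_points)

    out = []
    for chain in (chain_a, chain_b):
        isolated = sasa(chain.residues, probe=probe, n_points=n_points)
        dsasa = {}
        for res in chain.residues:
            drop = isolated[res.key] - complexed[res.key]
            if drop >= dsasa_threshold:
                dsasa[res.key] = drop
        out.append(
            InterfaceDefinition(
                chain_id=chain.chain_id,
                residues=list(dsasa),
                dsasa=dsasa,
                area=float(sum(dsasa.values())),
            )
        )
    return out[0], out[1]


def _atom_coords(residues: Iterable[Residue], names: Sequence[str] | None = None):
    coords, owners = [], []
    for res in residues:
        for atom in res.heavy_atoms():
            if names is None or atom.name in names:
                coords.append(atom.coord)
                owners.append((res, atom))
    return np.asarray(coords), owners


def _count_residue_pairs(pair: InterfacePair, predicate) -> int:
    count = 0
    for ra in pair.residues_a:
        for rb in pair.residues_b:
            if predicate(ra, rb):
                count += 1
    return count


def disulfide_bonds(pair: InterfacePair, ca_cutoff: float = 6.5) -> int:
    """Interchain Cys–Cys pairs with Cα–Cα distance ≤ 6.5 Å."""

    def is_bridge(ra: Residue, rb: Residue) -> bool:
        if ra.aa_type != "CYS" or rb.aa_type != "CYS":
            return False
        a, b = ra.atom("CA"), rb.atom("CA")
        return a is not None and b is not None and \
            float(np.linalg.norm(a.coord - b.coord)) <= ca_cutoff

    return _count_residue_pairs(pair, is_bridge)


def hydrophobic_contacts(
    pair: InterfacePair,
    cb_cutoff: float = 7.0,
    residue_types: frozenset = HYDROPHOBIC_RESIDUES,
) -> int:
    """Interchain pairs of hydrophobic residues with Cβ–Cβ < 7 Å
    (glycine has no Cβ and cannot contribute)."""

    def is_contact(ra: Residue, rb: Residue) -> bool:
        if ra.aa_type not in residue_types or rb.aa_type not in residue_types:
            return False
        a, b = ra.atom("CB"), rb.atom("CB")
        return a is not None and b is not None and \
            float(np.linalg.norm(a.coord - b.coord)) < cb_cutoff

    return _count_residue_pairs(pair, is_contact)


def short_contacts(
    pair: InterfacePair, radii: Mapping[str, float] | None = None
) -> int:
    """Residue pairs with at least one interchain heavy-atom pair closer
    than the sum of van der Waals radii (D = r − R < 0, strict)."""
    radii = radii or load_vdw_radii()

    def is_short(ra: Residue, rb: Residue) -> bool:
        for aa in ra.heavy_atoms():
            for ab in rb.heavy_atoms():
                r = float(np.linalg.norm(aa.coord - ab.coord))
                cap = radii.get(aa.element.upper(), 1.7) + radii.get(ab.element.upper(), 1.7)
                if r < cap:
                    return True
        return False

    return _count_residue_pairs(pair, is_short)


def salt_bridges(pair: InterfacePair, cutoff: float = 4.0) -> int:
    """Residue pairs of opposite charge with side-chain N and O within
    4 Å (inclusive); His counts as positive."""

    def charged_atoms(res: Residue, table) -> list:
        names = table.get(res.aa_type, ())
        return [res.atom(n) for n in names if res.atom(n) is not None]

    def is_bridge(ra: Residue, rb: Residue) -> bool:
        for pos, neg in ((ra, rb), (rb, ra)):
            ns = charged_atoms(pos, _POSITIVE_SIDECHAIN_N)
            os_ = charged_atoms(neg, _NEGATIVE_SIDECHAIN_O)
            for n_atom in ns:
                for o_atom in os_:
                    if float(np.linalg.norm(n_atom.coord - o_atom.coord)) <= cutoff:
                        return True
        return False

    return _count_residue_pairs(pair, is_bridge)


def electrostatic_interactions(pair: InterfacePair, cutoff: float = 6.0) -> int:
    """Charged side-chain N/O atom pairs of opposite sign within 6 Å.

    This feature has no canonical geometric definition; the 6 Å
    charged-atom criterion used here is this package's own convention.
    """
    count = 0
    for ra in pair.residues_a:
        for rb in pair.residues_b:
            for pos, neg in ((ra, rb), (rb, ra)):
                for n_name in _POSITIVE_SIDECHAIN_N.get(pos.aa_type, ()):
                    n_atom = pos.atom(n_name)
                    if n_atom is None:
                        continue
                    for o_name in _NEGATIVE_SIDECHAIN_O.get(neg.aa_type, ()):
                        o_atom = neg.atom(o_name)
                        if o_atom is None:
                            continue
                        if float(np.linalg.norm(n_atom.coord - o_atom.coord)) <= cutoff:
                            count += 1
    return count


def _donor_antecedent(res: Residue, donor) -> np.ndarray | None:
    best, best_d = None, np.inf
    for atom in res.heavy_atoms():
        if atom is donor:
            continue
        d = float(np.linalg.norm(atom.coord - donor.coord))
        if d < best_d:
            best, best_d = atom, d
    if best is not None and best_d <= 2.0:
        return best.coord
    return None


def hydrogen_bonds(
    pair: InterfacePair,
    distance_cutoff: float = 3.5,
    min_angle: float = 90.0,
) -> int:
    """Interchain hydrogen bonds, counted at atom-pair level.

    Hydrogens are absent from crystal structures, so a heavy-atom
    criterion is used: donor (N, or hydroxyl O of Ser/Thr/Tyr) to acceptor
    (any O) distance ≤ 3.5 Å and antecedent–donor–acceptor angle ≥ 90°.
    """

    def donors(res: Residue):
        for atom in res.heavy_atoms():
            if atom.element.upper() == "N":
                yield atom
            elif atom.element.upper() == "O" and res.aa_type in ("SER", "THR", "TYR") \
                    and atom.name in ("OG", "OG1", "OH"):
                yield atom

    def acceptors(res: Residue):
        for atom in res.heavy_atoms():
            if atom.element.upper() == "O":
                yield atom

    count = 0
    for donor_side, acceptor_side in (
        (pair.residues_a, pair.residues_b),
        (pair.residues_b, pair.residues_a),
    ):
        for rd in donor_side:
            for donor in donors(rd):
                antecedent = _donor_antecedent(rd, donor)
                for ra in acceptor_side:
                    for acceptor in acceptors(ra):
                        d = float(np.linalg.norm(donor.coord - acceptor.coord))
                        if d > distance_cutoff:
                            continue
                        if antecedent is not None:
                            ang = bond_angle(antecedent, donor.coord, acceptor.coord)
                            if ang < min_angle:
                                continue
                        count += 1
    return count


def vdw_contacts(
    pair: InterfacePair,
    tolerance: float = 1.0,
    radii: Mapping[str, float] | None = None,
    with_energy: bool = False,
):
    """Interchain heavy-atom pairs at van der Waals range:
    R ≤ r ≤ R + tolerance where R is the radius sum. Pairs with r < R are
    short contacts and excluded here by construction.

    With ``with_energy`` a unit-well-depth 6-12 energy
    Σ ε[(R/r)¹² − 2(R/r)⁶] over the counted pairs is returned alongside.
    """
    radii = radii or load_vdw_radii()
    coords_a, owners_a = _atom_coords(pair.residues_a)
    coords_b, owners_b = _atom_coords(pair.residues_b)
    count, energy = 0, 0.0
    for i, (ra, aa) in enumerate(owners_a):
        for j, (rb, ab) in enumerate(owners_b):
            r = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            cap = radii.get(aa.element.upper(), 1.7) + radii.get(ab.element.upper(), 1.7)
            if cap <= r <= cap + tolerance:
                count += 1
                ratio = cap / r
                energy += ratio**12 - 2.0 * ratio**6
    return (count, energy) if with_energy else count


def structural_segments(
    interface: Sequence, chain: Chain | None = None, max_gap: int = 5
) -> int:
    """Number of sequence segments in one side's interface residues:
    neighbours more than ``max_gap`` apart in the dense chain index start a
    new segment. Accepts residue keys with their chain, or raw indices."""
    if chain is not None:
        dense = chain.dense_index()
        indices = sorted(dense[k] for k in interface)
    else:
        indices = sorted(int(i) for i in interface)
    if not indices:
        return 0
    segments = 1
    for prev, nxt in zip(indices, indices[1:]):
        if nxt - prev > max_gap:
            segments += 1
    return segments


_ATOM_VOLUME = 20.1       # Å³, mean volume occupied per heavy atom
_SPHERE_RADIUS = 10.0     # Å


def protrusion_index(
    interface_residues: Iterable[Residue],
    context: Iterable[Residue],
    sphere_radius: float = _SPHERE_RADIUS,
    atom_volume: float = _ATOM_VOLUME,
) -> float:
    """Mean protrusion index (cx) over interface residues.

    Per atom, the number of heavy atoms (itself included) within a 10 Å
    sphere gives the occupied volume V_int = n × 20.1 Å³; cx is the
    empty-to-occupied ratio (V_sphere − V_int)/V_int. Residue values are
    atom means; the returned value is the residue mean.
    """
    from scipy.spatial import cKDTree

    context_coords = np.array(
        [a.coord for res in context for a in res.heavy_atoms()]
    )
    if len(context_coords) == 0:
        raise ValueError("protrusion index needs a non-empty context")
    tree = cKDTree(context_coords)
    v_sphere = 4.0 / 3.0 * np.pi * sphere_radius**3
    res_values = []
    for res in interface_residues:
        atom_values = []
        for atom in res.heavy_atoms():
            n_inside = len(tree.query_ball_point(atom.coord, sphere_radius))
            v_int = n_inside * atom_volume
            atom_values.append((v_sphere - v_int) / v_int)
        if atom_values:
            res_values.append(float(np.mean(atom_values)))
    if not res_values:
        raise ValueError("no interface residues with heavy atoms")
    return float(np.mean(res_values))


def planarity(
    interface_residues: Sequence[Residue], min_residues: int = 4
) -> float | None:
    """RMSD (Å) of interface atoms from their least-square plane; minor
    surfaces with fewer than ``min_residues`` residues are ignored
    (returns None)."""
    residues = list(interface_residues)
    if len(residues) < min_residues:
        return None
    coords = np.array([a.coord for r in residues for a in r.heavy_atoms()])
    plane = fit_lsq_plane(coords)
    distances = coords @ plane.normal + plane.offset
    return float(np.sqrt(np.mean(distances**2)))


@dataclass
class InterfaceFeatureSet:
    """The nine features plus area for one interface (DSI or NDSI)."""

    side_label: str
    area: float
    disulfides: int = 0
    hydrophobic_contacts: int = 0
    short_contacts: int = 0
    salt_bridges: int = 0
    hbonds: int = 0
    vdw_contacts: int = 0
    electrostatic: int = 0
    segments: int = 0
    protrusion_index: float = float("nan")
    planarity_rmsd: float | None = None
    extra: dict = field(default_factory=dict)

    _COUNT_FIELDS = (
        "disulfides", "hydrophobic_contacts", "short_contacts",
        "salt_bridges", "hbonds", "vdw_contacts", "electrostatic", "segments",
    )

    @property
    def normalized(self) -> dict[str, float]:
        """Counts (and protrusion index) divided by interface area;
        defined only for a positive area."""
        if not self.area > 0:
            raise ValueError("normalisation undefined for zero interface area")
        out = {name: getattr(self, name) / self.area for name in self._COUNT_FIELDS}
        out["protrusion_index"] = self.protrusion_index / self.area
        return out


def compute_feature_set(
    structure: Structure,
    pair: InterfacePair,
    area: float,
    side_label: str = "",
    segment_chain: Chain | None = None,
) -> InterfaceFeatureSet:
    """All interface features for one residue-pair set. ``segment_chain``
    (default: the chain of the first side) anchors segment counting."""
    chain = segment_chain or structure.chain(pair.residues_a[0].chain_id)
    context = list(structure.residues())
    count, energy = vdw_contacts(pair, with_energy=True)
    return InterfaceFeatureSet(
        side_label=side_label,
        area=area,
        disulfides=disulfide_bonds(pair),
        hydrophobic_contacts=hydrophobic_contacts(pair),
        short_contacts=short_contacts(pair),
        salt_bridges=salt_bridges(pair),
        hbonds=hydrogen_bonds(pair),
        vdw_contacts=count,
        electrostatic=electrostatic_interactions(pair),
        segments=structural_segments([r.key for r in pair.residues_a], chain),
        protrusion_index=protrusion_index(pair.residues_a + pair.residues_b, context),
        planarity_rmsd=planarity(pair.residues_a + pair.residues_b),
        extra={"vdw_energy": energy},
    )


def split_dsi_ndsi(
    structure: Structure,
    chain_pair: tuple[str, str],
    interface_pairs: Sequence[tuple],
    crossing_by_chain: Mapping[str, Sequence],
    margin: int = 1,
) -> dict[str, InterfacePair]:
    """Partition an interface into DSI and NDSI residue sets.

    A contact (a, b) belongs to the swapped-domain interface when either
    residue lies in (or within ``margin`` dense positions of) a crossing
    block — i.e. the contact involves an exchanged segment. The remaining
    contacts (body–body) form the NDSI. Returns ``{"DSI": InterfacePair,
    "NDSI": InterfacePair}``; either side may be empty.
    """
    chains = {cid: structure.chain(cid) for cid in chain_pair}
    by_key = {r.key: r for cid in chain_pair for r in chains[cid].residues}

    expanded: dict[str, set] = {}
    for cid in chain_pair:
        dense = chains[cid].dense_index()
        keys = list(dense)
        block = set()
        for k in crossing_by_chain.get(cid, ()):  # keys on that chain
            if k in dense:
                i = dense[k]
                for j in range(max(0, i - margin), min(len(keys), i + margin + 1)):
                    block.add(keys[j])
        expanded[cid] = block

    dsi_a, dsi_b, ndsi_a, ndsi_b = {}, {}, {}, {}
    for ka, kb, _ in interface_pairs:
        swappy = (
            ka in expanded.get(ka[0], set())
            or kb in expanded.get(kb[0], set())
        )
        (dsi_a if swappy else ndsi_a).setdefault(ka)
        (dsi_b if swappy else ndsi_b).setdefault(kb)
    return {
        "DSI": InterfacePair([by_key[k] for k in dsi_a], [by_key[k] for k in dsi_b]),
        "NDSI": InterfacePair([by_key[k] for k in ndsi_a], [by_key[k] for k in ndsi_b]),
    }


def compare_dsi_ndsi(paired_sets: Sequence[tuple[InterfaceFeatureSet, InterfaceFeatureSet]]):
    """Paired comparison of per-Å²-normalised features across entries.

    Returns a DataFrame with the DSI and NDSI means, the paired t
    statistic and the two-sided p-value per feature; pairs with zero
    difference variance are flagged degenerate (p undefined).
    """
    import pandas as pd
    from scipy import stats

    if len(paired_sets) < 2:
        raise ValueError("paired comparison needs at least 2 entry pairs")
    features = list(InterfaceFeatureSet._COUNT_FIELDS) + ["protrusion_index"]
    rows = []
    for name in features:
        dsi = np.array([p[0].normalized[name] for p in paired_sets])
        ndsi = np.array([p[1].normalized[name] for p in paired_sets])
        diff = dsi - ndsi
        if np.allclose(diff.std(ddof=1), 0.0):
            rows.append({"feature": name, "mean_dsi": dsi.mean(),
                         "mean_ndsi": ndsi.mean(), "t": np.nan, "p": np.nan,
                         "degenerate": True})
            continue
        t, p = stats.ttest_rel(dsi, ndsi)
        rows.append({"feature": name, "mean_dsi": dsi.mean(),
                     "mean_ndsi": ndsi.mean(), "t": float(t), "p": float(p),
                     "degenerate": False})
    return pd.DataFrame(rows).set_index("feature")
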