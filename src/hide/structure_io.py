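"""Structure input/output: PDB/mmCIF reading into a light domain model,
resolution filtering, and JSON/TSV report writing.

Parsing is delegated to gemmi; this module only flattens the result into
the minimal hierarchy the analysis code needs (chains → residues → heavy
atoms, author numbering with insertion codes, highest-occupancy altloc,
first model only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import gemmi

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "FormatError",
    "EmptyStructureError",
    "ResolutionVerdict",
    "STANDARD_AA3",
    "NONSTANDARD_PARENT",
    "read_structure",
    "structure_from_gemmi",
    "filter_by_resolution",
    "write_pdb",
    "write_report",
    "read_report",
    "fetch_pdb",
]


class FormatError(ValueError):
    """Input file could not be parsed as PDB or mmCIF."""


class EmptyStructureError(ValueError):
    """Parsed file contains no protein residues."""


STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Common chemically modified residues mapped to their standard parent.
#: Anything else non-standard is kept for geometry but flagged.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "MLY": "LYS",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.isfinite(c).all():
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol required")
        self.coord = c


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa_type: str
    atoms: list[Atom] = field(default_factory=list)
    standard: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        """Public residue identifier: (chain id, author number, icode)."""
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.aa_type, "X")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def dense_index(self) -> dict[tuple[str, int, str], int]:
        """0-based position of each residue key in chain order; all
        sequence-gap arithmetic uses this, never author numbers."""
        return {r.key: i for i, r in enumerate(self.residues)}

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coord for r in self.residues if r.atom("CA")])


@dataclass
class Structure:
    pdb_id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: float | None = None
    assembly_note: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.pdb_id}")

    def residues(self) -> Iterable[Residue]:
        for c in self.chains:
            yield from c.residues


def _resolve_altlocs(raw_atoms) -> list:
    """Keep one atom per name: the highest-occupancy altloc (first wins a tie)."""
    best: dict[str, object] = {}
    order: list[str] = []
    for a in raw_atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [best[n] for n in order]


def structure_from_gemmi(st: gemmi.Structure, model_policy: str = "first") -> Structure:
    if model_policy not in ("first", "error-on-multi"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    if len(st) == 0:
        raise EmptyStructureError(f"{st.name}: no models")
    if model_policy == "error-on-multi" and len(st) > 1:
        raise ValueError(f"{st.name}: {len(st)} models present (multi-model input refused)")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa:
                continue  # waters, ligands, nucleic acids
            aa = gres.name.upper()
            standard = aa in STANDARD_AA3
            if not standard and aa in NONSTANDARD_PARENT:
                aa = NONSTANDARD_PARENT[aa]
            atoms = []
            for ga in _resolve_altlocs(list(gres)):
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name or "C",
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                    )
                )
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    aa_type=aa,
                    atoms=atoms,
                    standard=standard,
                )
            )
        if residues:
            keys = [(r.seq_number, r.insertion_code) for r in residues]
            if keys != sorted(keys):
                logger.warning(
                    "chain %s of %s: residue order not monotone in (number, icode)",
                    gchain.name, st.name,
                )
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    structure = Structure(
        pdb_id=(st.name or "").lower(),
        chains=chains,
        resolution=st.resolution if st.resolution and st.resolution > 0 else None,
        assembly_note=st.spacegroup_hm or "",
    )
    if not any(r.atom("CA") for r in structure.residues()):
        raise EmptyStructureError(f"{st.name}: no protein residues with a CA atom")
    return structure


def read_structure(path: str | Path, model_policy: str = "first") -> Structure:
    """Read a PDB or mmCIF file into the domain model.

    Waters and hetero compounds are dropped, altlocs resolved to highest
    occupancy, and only the first model is used (``model_policy='first'``;
    ``'error-on-multi'`` refuses NMR-style ensembles).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not parseable as PDB/mmCIF ({exc})") from exc
    st.setup_entities()
    return structure_from_gemmi(st, model_policy=model_policy)


@dataclass(frozen=True)
class ResolutionVerdict:
    accepted: bool
    reason: str  # "ok" | "too-low" | "no-resolution"


def filter_by_resolution(structure: Structure, max_res: float) -> ResolutionVerdict:
    """Accept iff a resolution is recorded and is ≤ ``max_res`` Å.

    Structures without a recorded resolution are rejected with the distinct
    ``no-resolution`` flag so callers can report them separately.
    """
    if structure.resolution is None:
        return ResolutionVerdict(accepted=False, reason="no-resolution")
    if structure.resolution > max_res:
        return ResolutionVerdict(accepted=False, reason="too-low")
    return ResolutionVerdict(accepted=True, reason="ok")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.pdb_id or "XXXX"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.aa_type
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.occ = atom.occupancy
                ga.pos = gemmi.Position(*map(float, atom.coord))
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the domain model as a PDB file (via gemmi)."""
    _to_gemmi(structure).write_pdb(str(path))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {_key(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def _key(k):
    if isinstance(k, (list, tuple)):
        return "/".join(str(x) for x in k)
    return str(k)


def write_report(result, path: str | Path, format: str = "json") -> None:
    """Serialize an analysis record to JSON or TSV.

    JSON round-trips any nested dataclass/dict/array record. TSV writes one
    row per feature for a flat mapping, or one row per record for a list of
    mappings. An empty record produces a valid empty document.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_jsonable(result), indent=2) + "\n")
    elif format == "tsv":
        import pandas as pd

        data = _jsonable(result)
        if isinstance(data, Mapping):
            frame = pd.DataFrame(
                [(k, v) for k, v in data.items()], columns=["feature", "value"]
            )
        elif isinstance(data, list):
            frame = pd.DataFrame(data)
        else:
            frame = pd.DataFrame({"value": [data]})
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json"):
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())
    if format == "tsv":
        import pandas as pd

        return pd.read_csv(path, sep="\t")
    raise ValueError(f"unknown report format {format!r}")


def fetch_pdb(pdb_id: str, dest_dir: str | Path = ".") -> Path:
    """Optional convenience: download a PDB entry from the wwPDB.

    No core operation depends on this helper; it exists so users with
    network access can pull the worked-example entries.
    """
    import urllib.request

    pdb_id = pdb_id.lower()
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=30) as response:
        dest.write_bytes(response.read())
    return dest
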