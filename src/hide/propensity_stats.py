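"""Sequence and conformation statistics for hinge regions.

Amino-acid propensity in a structural context s (helix, sheet, loop or
hinge) is the relative enrichment

    P_{i,s} = (n_{i,s} / N_s) / (n_i / N)

of residue type i in s compared with its overall frequency; by
construction the frequency-weighted mean Σ_i P_{i,s}·(n_i/N) is exactly 1
in every context. Hinge propensities are compared against the secondary
structure contexts by Pearson correlation, and the hinge/loop preference
of a residue type is summarised by the normalised propensity
ln(f_h/f_l) = ln(n_hinge_i / n_loop_i).

A published 20×4 reference propensity table (helix/sheet/loop/hinge) ships
with the package for desk-scale correlation analyses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import DihedralPair, quadrant_of

__all__ = [
    "PropensityTable",
    "QuadrantDistribution",
    "propensity",
    "propensity_table",
    "assign_secondary_structure",
    "context_counts",
    "propensity_correlation",
    "normalized_hinge_propensity",
    "load_reference_propensities",
    "quadrant_distribution",
    "consecutive_quadrant_pairs",
    "hinge_dataset_filter",
    "QUADRANTS",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


def propensity(n_is: float, n_s: float, n_i: float, n_total: float) -> float:
    """P_{i,s} = (n_{i,s}/N_s) / (n_i/N)."""
    if n_s <= 0 or n_i <= 0 or n_total <= 0:
        raise ValueError("propensity undefined for zero denominators")
    return (n_is / n_s) / (n_i / n_total)


@dataclass
class PropensityTable:
    """Propensities per amino acid and context with their source counts."""

    propensities: pd.DataFrame   # index aa, one column per context
    counts: pd.DataFrame         # n_{i,s} with an n_total column
    totals: pd.Series            # N_s per context, plus overall N

    def column(self, context: str) -> np.ndarray:
        return self.propensities[context].to_numpy()


def propensity_table(counts: pd.DataFrame) -> PropensityTable:
    """Build a :class:`PropensityTable` from a counts frame with an ``aa``
    column, one ``n_<context>`` column per context, and ``n_total``
    (occurrences of each type over the whole dataset)."""
    frame = counts.set_index("aa") if "aa" in counts.columns else counts.copy()
    if "n_total" not in frame.columns:
        raise ValueError("counts need an n_total column")
    contexts = [c[2:] for c in frame.columns if c.startswith("n_") and c != "n_total"]
    n_i = frame["n_total"].astype(float)
    n = float(n_i.sum())
    table = {}
    totals = {}
    for ctx in contexts:
        n_is = frame[f"n_{ctx}"].astype(float)
        n_s = float(n_is.sum())
        totals[ctx] = n_s
        table[ctx] = (n_is / n_s) / (n_i / n)
    totals["all"] = n
    return PropensityTable(
        propensities=pd.DataFrame(table, index=frame.index),
        counts=frame,
        totals=pd.Series(totals),
    )


def assign_secondary_structure(residues: Sequence) -> list[str]:
    """Helix/sheet/loop assignment from backbone torsions alone.

    A residue is ``helix`` in the α-region (φ ∈ [−100, −30], ψ ∈ [−77, −7]),
    ``sheet`` in the extended β-region (φ ∈ [−180, −90], ψ ≥ 90 or ≤ −150)
    and ``loop`` otherwise (including undefined termini). This is a
    deliberately simple torsion-region assigner; externally computed
    assignments can always be supplied as a counts column instead.
    """
    from .geometry import backbone_dihedrals

    out = []
    for d in backbone_dihedrals(residues):
        if not d.defined:
            out.append("loop")
        elif -100.0 <= d.phi <= -30.0 and -77.0 <= d.psi <= -7.0:
            out.append("helix")
        elif -180.0 <= d.phi <= -90.0 and (d.psi >= 90.0 or d.psi <= -150.0):
            out.append("sheet")
        else:
            out.append("loop")
    return out


def context_counts(
    chains: Sequence,
    hinge_keys: set | None = None,
    assignments: Sequence[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-amino-acid context counts (n_helix/n_sheet/n_loop/n_hinge and
    n_total) over a set of chains, ready for :func:`propensity_table`.

    Hinge residues (``hinge_keys``) are counted in the hinge context
    instead of their secondary-structure context. ``assignments`` may
    supply precomputed per-chain helix/sheet/loop labels; otherwise the
    torsion-based assigner is used."""
    hinge_keys = hinge_keys or set()
    rows: dict[str, dict[str, int]] = {}
    for ci, chain in enumerate(chains):
        labels = (
            list(assignments[ci]) if assignments is not None
            else assign_secondary_structure(chain.residues)
        )
        for res, label in zip(chain.residues, labels):
            aa = res.one_letter
            if aa == "X":
                continue  # non-standard residues excluded from statistics
            entry = rows.setdefault(
                aa, {"n_helix": 0, "n_sheet": 0, "n_loop": 0, "n_hinge": 0,
                     "n_total": 0}
            )
            context = "hinge" if res.key in hinge_keys else label
            entry[f"n_{context}"] += 1
            entry["n_total"] += 1
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "aa"
    return frame.reset_index()


def propensity_correlation(col_a: Sequence[float], col_b: Sequence[float]) -> float:
    """Pearson product-moment correlation between two propensity columns."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def normalized_hinge_propensity(
    n_hinge_i: float, n_loop_i: float, n_total_i: float | None = None
) -> float:
    """ln(f_h/f_l) for one residue type: f_h = n_hinge_i/n_total_i and
    f_l = n_loop_i/n_total_i, so the totals cancel and the value is
    ln(n_hinge_i/n_loop_i). Zero counts are an error — no smoothing is
    applied silently."""
    if n_hinge_i <= 0 or n_loop_i <= 0:
        raise ValueError("ln(f_h/f_l) undefined for zero hinge or loop count")
    if n_total_i is not None and n_total_i < max(n_hinge_i, n_loop_i):
        raise ValueError("n_total_i smaller than a context count")
    return float(np.log(n_hinge_i / n_loop_i))


def load_reference_propensities() -> pd.DataFrame:
    """The packaged published 20×4 propensity matrix (index: one-letter
    amino acid; columns helix, sheet, loop, hinge)."""
    with importlib.resources.files("hide.data").joinpath(
        "reference_propensities.csv"
    ).open() as handle:
        return pd.read_csv(handle, index_col="aa")


@dataclass
class QuadrantDistribution:
    """Percent of residues per Ramachandran quadrant (of defined pairs)."""

    percent: dict[str, float]
    n: int
    excluded_glycine: bool = False

    def __getitem__(self, quadrant: str) -> float:
        return self.percent[quadrant]


def quadrant_distribution(
    pairs: Iterable[DihedralPair],
    aa_types: Sequence[str] | None = None,
    exclude_glycine: bool = False,
) -> QuadrantDistribution:
    """Percent distribution of (φ,ψ) pairs over the four quadrants.

    Undefined pairs are excluded from the denominator; with
    ``exclude_glycine`` the parallel ``aa_types`` sequence (3- or 1-letter)
    is used to drop glycine residues."""
    pairs = list(pairs)
    if exclude_glycine:
        if aa_types is None:
            raise ValueError("exclude_glycine requires aa_types")
        pairs = [p for p, aa in zip(pairs, aa_types)
                 if str(aa).upper() not in ("G", "GLY")]
    defined = [p for p in pairs if p.defined]
    if not defined:
        raise ValueError("no defined (phi, psi) pairs to tally")
    tally = {q: 0 for q in QUADRANTS}
    for p in defined:
        tally[quadrant_of(p)] += 1
    n = len(defined)
    return QuadrantDistribution(
        percent={q: 100.0 * c / n for q, c in tally.items()},
        n=n,
        excluded_glycine=exclude_glycine,
    )


def consecutive_quadrant_pairs(pairs: Sequence[DihedralPair]) -> dict[str, float]:
    """Quadrant preferences of adjacent hinge residues: the fraction of
    adjacent defined (φ,ψ) pairs falling jointly in each quadrant, plus a
    ``mixed`` class for neighbours in different quadrants."""
    if len(pairs) < 2:
        raise ValueError("need a hinge of at least 2 residues")
    classes = {q: 0 for q in QUADRANTS}
    classes["mixed"] = 0
    n = 0
    for a, b in zip(pairs, pairs[1:]):
        if not (a.defined and b.defined):
            continue
        qa, qb = quadrant_of(a), quadrant_of(b)
        classes[qa if qa == qb else "mixed"] += 1
        n += 1
    if n == 0:
        raise ValueError("no adjacent defined pairs")
    return {k: v / n for k, v in classes.items()}


def hinge_dataset_filter(
    entries: Iterable,
    max_resolution: float = 2.0,
    max_hinge_length: int = 5,
):
    """Conformational-analysis subset: keep entries from crystal
    structures at resolution better than 2 Å with hinges of at most five
    residues. Entries are any records with ``resolution`` and
    ``hinge_length`` attributes or keys; returns (kept, excluded) where
    excluded maps reason → entries."""

    def get(entry, name):
        if hasattr(entry, name):
            return getattr(entry, name)
        return entry[name]

    kept, excluded = [], {"resolution": [], "no-resolution": [], "too-long": []}
    for entry in entries:
        resolution = get(entry, "resolution")
        length = get(entry, "hinge_length")
        if length > max_hinge_length:
            excluded["too-long"].append(entry)
        elif resolution is None:
            excluded["no-resolution"].append(entry)
        elif resolution >= max_resolution:
            excluded["resolution"].append(entry)
        else:
            kept.append(entry)
    return kept, excluded
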