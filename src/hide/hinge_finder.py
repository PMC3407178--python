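"""Hinge localisation by successive superposition against a non-swapped
homologue.

The swapped protomer and its best non-swapped homologue are first
superposed globally (sequence-alignment-seeded Kabsch with iterative
trimming of deviating residue pairs); the swapped region and the hinge are
left unaligned. A second superposition of the unaligned region alone then
re-aligns the swapped domain internally, leaving only the hinge without a
consistent equivalence. Residues unaligned in both rounds seed the hinge,
and backbone Δ(φ,ψ) against the homologue equivalents extends it through
contiguous runs of conformational change above a threshold (default 20°).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import (
    SuperpositionResult,
    backbone_dihedrals,
    delta_phi_psi,
    kabsch_superpose,
)
from .structure_io import Chain

__all__ = [
    "HomologueRecord",
    "HingeAnnotation",
    "NoHomologueError",
    "select_best_homologue",
    "superpose_and_map",
    "find_hinge",
]


class NoHomologueError(ValueError):
    """No usable non-swapped homologue survives the identity/E-value and
    swap-status filters."""


@dataclass(frozen=True)
class HomologueRecord:
    """One hit from a (precomputed) homologue search."""

    query_id: str
    pdb_id: str
    chain: str
    percent_identity: float
    e_value: float
    source: str = "sequence"

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity must be in [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be ≥ 0")


def select_best_homologue(
    records: Sequence[HomologueRecord],
    swapped_flags: Mapping[str, bool],
    min_identity: float = 30.0,
    max_e_value: float = 1e-3,
) -> HomologueRecord:
    """Best non-swapped homologue by percent identity.

    Multiple occurrences of the same entry are collapsed to their average
    identity before filtering (identity > ``min_identity``, E-value <
    ``max_e_value``) and before dropping entries flagged as swapped.
    """
    if not records:
        raise NoHomologueError("empty homologue record list")
    grouped: dict[tuple[str, str], list[HomologueRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.pdb_id, rec.chain), []).append(rec)
    collapsed = []
    for (pdb_id, chain), group in grouped.items():
        identity = float(np.mean([r.percent_identity for r in group]))
        collapsed.append(
            HomologueRecord(
                query_id=group[0].query_id, pdb_id=pdb_id, chain=chain,
                percent_identity=identity,
                e_value=min(r.e_value for r in group),
                source=group[0].source,
            )
        )
    survivors = [
        r for r in collapsed
        if r.percent_identity > min_identity
        and r.e_value < max_e_value
        and not swapped_flags.get(r.pdb_id, False)
    ]
    if not survivors:
        raise NoHomologueError(
            "no non-swapped homologue above %.0f%% identity with E < %g"
            % (min_identity, max_e_value)
        )
    return max(survivors, key=lambda r: r.percent_identity)


def _sequence_equivalences(query: Chain, homologue: Chain) -> list[tuple]:
    """Residue-key pairs from a global sequence alignment (BLOSUM62),
    restricted to positions where both residues have a Cα."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    alignment = aligner.align(query.sequence().replace("X", "A"),
                              homologue.sequence().replace("X", "A"))[0]
    pairs = []
    for (q0, q1), (h0, h1) in zip(*alignment.aligned):
        for qi, hi in zip(range(q0, q1), range(h0, h1)):
            qres, hres = query.residues[qi], homologue.residues[hi]
            if qres.atom("CA") is not None and hres.atom("CA") is not None:
                pairs.append((qres.key, hres.key))
    return pairs


def superpose_and_map(
    query: Chain,
    homologue: Chain,
    trim_cutoff: float = 3.5,
    max_iter: int = 50,
    equivalences: Sequence[tuple] | None = None,
) -> SuperpositionResult:
    """Iteratively trimmed rigid superposition of two chains.

    Starting from sequence-alignment equivalences (or a user-imported
    pairing, e.g. parsed from an external structural-alignment output),
    pairs deviating by more than ``trim_cutoff`` Å are discarded and the
    superposition repeated until the surviving pair set is a fixed point.
    ``result.equivalences`` holds the surviving residue-key pairs.
    """
    if len(query) < 20 or len(homologue) < 20:
        raise ValueError("superposition needs chains of at least 20 residues")
    pairs = list(equivalences) if equivalences is not None else \
        _sequence_equivalences(query, homologue)
    q_by, h_by = {r.key: r for r in query}, {r.key: r for r in homologue}
    current = [
        (qk, hk) for qk, hk in pairs
        if qk in q_by and hk in h_by
        and q_by[qk].atom("CA") is not None and h_by[hk].atom("CA") is not None
    ]
    if len(current) < 3:
        raise ValueError("fewer than 3 alignable residue pairs")

    result, current = _trim_superpose(q_by, h_by, current, trim_cutoff, max_iter)
    result.equivalences = current
    return result


def _trim_superpose(q_by, h_by, pairs, trim_cutoff: float, max_iter: int = 50):
    """Iteratively trimmed Kabsch fit over residue-key ``pairs``.

    At each round pairs deviating more than the cutoff are dropped, but
    never more than the worst half at once — a single global fit of two
    conformers can leave *every* pair above the cutoff, and the gradual
    schedule lets the fit settle onto the conserved core instead of
    emptying the set. Stops at a fixed point or when fewer than 3 pairs
    would remain."""
    current = list(pairs)
    result = None
    for _ in range(max_iter):
        moving = np.array([q_by[qk].atom("CA").coord for qk, _ in current])
        fixed = np.array([h_by[hk].atom("CA").coord for _, hk in current])
        result = kabsch_superpose(moving, fixed)
        deviation = np.linalg.norm(result.transform(moving) - fixed, axis=1)
        threshold = max(trim_cutoff, float(np.median(deviation)))
        kept = [pair for pair, d in zip(current, deviation) if d <= threshold]
        if kept == current and threshold > trim_cutoff:
            # all pairs tied at the median: drop the single worst
            worst = int(np.argmax(deviation))
            kept = [p for j, p in enumerate(current) if j != worst]
        if len(kept) < 3 or kept == current:
            break
        current = kept
    # membership pass under the converged transform: scattered pairs that
    # sit within a slightly looser bound are re-included (hysteresis), so
    # aligned/unaligned boundaries are clean and borderline residues at
    # the junction do not flap into the unaligned set
    moving = np.array([q_by[qk].atom("CA").coord for qk, _ in pairs])
    fixed = np.array([h_by[hk].atom("CA").coord for _, hk in pairs])
    deviation = np.linalg.norm(result.transform(moving) - fixed, axis=1)
    final = [pair for pair, d in zip(pairs, deviation) if d <= 1.3 * trim_cutoff]
    if len(final) >= 3:
        current = final
    return result, current


@dataclass
class HingeAnnotation:
    """Hinge interval on the swapped protomer with its homologue
    equivalent, per-residue Δ(φ,ψ), and a trace of which criterion placed
    each residue."""

    status: str  # "found" | "no-deviation" | "missing-swapped-domain"
    query_interval: tuple | None = None        # (first key, last key)
    homologue_interval: tuple | None = None
    per_residue_delta: dict = field(default_factory=dict)
    method_trace: dict = field(default_factory=dict)
    excluded_from_stats: bool = False

    @property
    def found(self) -> bool:
        return self.status == "found"


def _runs(indices: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for i in sorted(indices):
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def find_hinge(
    query: Chain,
    homologue: Chain,
    delta_threshold: float = 20.0,
    flank: int = 10,
    crossing_block: Sequence[tuple] | None = None,
    trim_cutoff: float = 3.5,
    equivalences: Sequence[tuple] | None = None,
) -> HingeAnnotation:
    """Locate the hinge of a swapped protomer against a non-swapped
    homologue chain.

    ``crossing_block`` (residue keys of the query chain on the wrong side
    of the partner's interface plane) selects which unaligned region is the
    swap; without it the region of maximal deviation is used and flagged in
    the trace. The final interval contains exactly the residues that were
    unaligned in both superposition rounds or that show Δ(φ,ψ) above
    ``delta_threshold`` in a contiguous run, scanning at most ``flank``
    residues beyond the seed on each side.
    """
    seq_pairs = list(equivalences) if equivalences is not None else \
        _sequence_equivalences(query, homologue)
    q_to_h = dict(seq_pairs)
    dense = query.dense_index()
    keys = [r.key for r in query.residues]

    # a swapped segment absent from the homologue cannot be superposed
    if crossing_block:
        covered = sum(1 for k in crossing_block if k in q_to_h)
        if covered < 0.5 * len(crossing_block):
            return HingeAnnotation(status="missing-swapped-domain")

    round1 = superpose_and_map(query, homologue, trim_cutoff=trim_cutoff,
                               equivalences=seq_pairs)
    aligned1 = {qk for qk, _ in round1.equivalences}
    unaligned1 = [dense[k] for k in keys if k not in aligned1]
    if not unaligned1:
        return HingeAnnotation(status="no-deviation")

    runs = _runs(unaligned1)
    chosen, fallback = None, False
    if crossing_block:
        block = {dense[k] for k in crossing_block if k in dense}
        for run in runs:
            grown = set(range(run[0] - 1, run[-1] + 2))
            if grown & block:
                chosen = run if chosen is None or len(run) > len(chosen) else chosen
    if chosen is None:
        # no verdict available: take the unaligned region deviating most
        fallback = True
        h_by = {r.key: r for r in homologue}

        def mean_dev(run):
            devs = []
            for i in run:
                qk = keys[i]
                if qk in q_to_h and query.residues[i].atom("CA") is not None:
                    moved = round1.transform(query.residues[i].atom("CA").coord[None, :])
                    devs.append(
                        float(np.linalg.norm(moved[0] - h_by[q_to_h[qk]].atom("CA").coord))
                    )
            return np.mean(devs) if devs else 0.0

        chosen = max(runs, key=mean_dev)

    run_keys = [keys[i] for i in chosen]
    if not crossing_block:
        covered = sum(1 for k in run_keys if k in q_to_h)
        if covered < 0.5 * len(run_keys):
            return HingeAnnotation(status="missing-swapped-domain")

    # round 2: superpose only the unaligned (swap-containing) region
    run_pairs = [(qk, q_to_h[qk]) for qk in run_keys if qk in q_to_h]
    if len(run_pairs) >= 3:
        q_by = {r.key: r for r in query}
        h_by = {r.key: r for r in homologue}
        _, current = _trim_superpose(q_by, h_by, run_pairs, trim_cutoff)
        aligned2 = {qk for qk, _ in current} if len(current) >= 3 else set()
    else:
        aligned2 = set()
    core = [i for i in chosen if keys[i] not in aligned2]

    # Δ(φ,ψ) between query residues and homologue equivalents
    q_dihedrals = backbone_dihedrals(query.residues)
    h_dihedrals = backbone_dihedrals(homologue.residues)
    h_index = homologue.dense_index()
    deltas: dict = {}
    for i, qk in enumerate(keys):
        if qk in q_to_h:
            deltas[qk] = delta_phi_psi(q_dihedrals[i], h_dihedrals[h_index[q_to_h[qk]]])

    def hot(i: int) -> bool:
        d = deltas.get(keys[i])
        return d is not None and d > delta_threshold

    if not core:
        # round 2 re-aligned the whole region: the hinge sits at the
        # junction between the round-1 aligned body and the unaligned
        # region — take the contiguous Δ-hot run nearest that junction
        junction = chosen[0] if chosen[0] > 0 else chosen[-1]
        near = range(max(0, junction - flank), min(len(keys), junction + flank + 1))
        hot_runs = _runs([i for i in near if hot(i)])
        if hot_runs:
            # strongest contiguous conformational change near the junction:
            # total Δ excess over the threshold, discounted with distance,
            # so a real multi-residue hinge beats a one-residue noise blip
            def score(run):
                excess = sum(deltas[keys[i]] - delta_threshold for i in run)
                gap = min(abs(i - junction) for i in run)
                return excess / (1.0 + gap)

            core = max(hot_runs, key=score)
        else:
            core = [junction]

    lo, hi = min(core), max(core)
    while lo - 1 >= max(0, min(core) - 1 - flank) and hot(lo - 1):
        lo -= 1
    while hi + 1 <= min(len(keys) - 1, max(core) + 1 + flank) and hot(hi + 1):
        hi += 1

    trace = {}
    for i in range(lo, hi + 1):
        trace[keys[i]] = {
            "unaligned_round1": keys[i] not in aligned1,
            "unaligned_round2": i in chosen and keys[i] not in aligned2,
            "delta": deltas.get(keys[i]),
            "core": i in core,
            "fallback_region_choice": fallback,
        }

    h_keys = [q_to_h[keys[i]] for i in range(lo, hi + 1) if keys[i] in q_to_h]
    return HingeAnnotation(
        status="found",
        query_interval=(keys[lo], keys[hi]),
        homologue_interval=(h_keys[0], h_keys[-1]) if h_keys else None,
        per_residue_delta={k: v for k, v in deltas.items() if v is not None},
        method_trace=trace,
        excluded_from_stats=(hi - lo + 1) > 5,
    )
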