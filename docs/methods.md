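# Methods

This note documents the models and procedures implemented in `hide`, the
parameters that matter, the synthetic-data generator, and the numerical
and design choices made where the method description leaves room.

## Swap classification

An interface residue pair is any residue pair of two chains whose minimum
interatomic distance is below a cutoff (default 7 Å over heavy atoms;
Cα-only is available via `atom_mode="ca"` since the original distance
criterion's atom set is ambiguous). The classification plane is always
fitted through the **Cα** atoms of one chain's interface residues, as a
total-least-squares (orthogonal-residual) plane: the normal is the
smallest-singular-value right singular vector of the centred coordinate
matrix, with the sign convention that its first nonzero component is
positive. Points closer than `epsilon` (default 10⁻⁶ Å) to the plane are
treated as on-plane and never count as crossers. Collinear interface
patches (second singular value ≤ 10⁻⁸ of the first) have no unique plane
and yield an `inconclusive` verdict.

A pair is swapped when the partner's Cα signs are mixed **and** the
minority-side residues form one sequence-contiguous block, with internal
gaps of at most `max_gap` residues (default 2, tolerating missing
density) in the dense chain index. The test is symmetrised — each chain's
plane tests the other — and a pair is swapped if either direction shows a
contiguous crossing block. Ties between the two half-spaces are broken
toward the side of the N-terminus. Chains shorter than 10 residues
(peptides, tags) are skipped. For complexes, every chain pair with a
non-empty interface is classified and the complex is swapped iff any pair
is.

## Hinge identification

The non-swapped homologue is chosen by percent identity after collapsing
duplicate hits to their mean identity and filtering at identity > 30 %,
E-value < 10⁻³, and non-swapped status.

Superposition is a sequence-alignment-seeded (global BLOSUM62, gap
−11/−1) Kabsch fit with iterative trimming: pairs deviating beyond
`trim_cutoff` (default 3.5 Å) are discarded — never more than the worst
half per round, because a single global fit of two conformers can leave
*every* pair above the cutoff — and the fit repeats to a fixed point.
After convergence a membership pass re-admits any pair within 1.3 ×
`trim_cutoff` under the final transform; the hysteresis keeps
aligned/unaligned boundaries clean instead of letting borderline
junction residues flap between the sets. Externally computed structural
alignments can be imported as explicit residue-pair lists to reproduce
other tool chains.

The hinge search then proceeds in two rounds. Round 1 superposes the
whole chains; the contiguous unaligned region overlapping (or adjacent
to) the classifier's crossing block is the swap-containing candidate —
without a verdict, the region of maximal deviation is used and flagged in
the trace. Round 2 superposes only that region, re-aligning the swapped
domain internally; residues unaligned in both rounds seed the hinge.
When round 2 re-aligns everything (small swap-domain reorientations),
the seed is instead the contiguous run of residues with Δ(φ,ψ) above
threshold nearest the round-1 aligned/unaligned junction, scored by total
Δ-excess discounted with distance so a genuine multi-residue hinge beats
a one-residue noise excursion. Finally the interval is extended outward
through contiguous Δ(φ,ψ) > `delta_threshold` (default 20°) residues,
scanning at most `flank` (default 10) residues beyond the seed; the
extension never jumps across a sub-threshold residue. Shrinking `flank`
can therefore only shorten the interval.

Δ(φ,ψ) is the Euclidean norm of the wrapped (Δφ, Δψ) vector. The exact
functional form behind the published 20° criterion is not recoverable
from its source; the Euclidean combination is symmetric, reduces to |Δφ|
or |Δψ| when the other component vanishes, is a metric on the torus, and
is compatible with a single scalar threshold. Both the form's threshold
and the flank width are configurable.

Outcomes: `found` (with query and homologue intervals, per-residue Δ and
a per-residue method trace), `no-deviation` (query indistinguishable from
the homologue), and `missing-swapped-domain` (the homologue lacks
coordinates for at least half of the swapped segment — such cases cannot
be compared). Hinges longer than five residues are reported but flagged
`excluded_from_stats`, mirroring the length filter used for
conformational statistics (together with the < 2 Å resolution filter in
`hinge_dataset_filter`).

## Ramachandran quadrants

Q1 is the upper-left quadrant (φ < 0, ψ > 0; extended/β), Q2 upper right
(α-L), Q3 lower right, Q4 lower left (α-R). Boundary values (exact 0 or
±180°) are assigned with a negative-φ / positive-ψ preference. Quadrant
percentages are taken over defined (φ,ψ) pairs only; glycine can be
excluded when a parallel residue-type vector is supplied.

## Interface features

Interfaces are defined by solvent-accessibility loss: per-residue ΔSASA =
SASA(isolated chain) − SASA(two-chain complex), interface membership at
ΔSASA ≥ 1 Å², interface area = Σ ΔSASA over one side's interface
residues. SASA is Shrake–Rupley with 960 deterministic golden-spiral
sphere points, probe 1.4 Å, Bondi-type radii from a packaged CSV;
hydrogens are ignored and coincident duplicate atoms count once.

Feature definitions (counting level in parentheses): disulfides —
Cys–Cys Cα ≤ 6.5 Å (residue pairs); hydrophobic contacts — Cβ–Cβ < 7 Å
between Ala/Leu/Ile/Val/Trp/Tyr/Phe (residue pairs; the set is
configurable, and Trp is taken as the intended third aromatic of the
published list); short contacts — any heavy-atom pair with r − R < 0,
strict, where R is the radius sum (residue pairs); salt bridges —
side-chain N of Lys/Arg/His (His counted protonatable) to side-chain O of
Asp/Glu at ≤ 4.0 Å inclusive (residue pairs); hydrogen bonds —
donor–acceptor heavy atoms ≤ 3.5 Å with antecedent–donor–acceptor angle
≥ 90°, hydrogens ignored (atom pairs); van der Waals contacts — heavy
atom pairs with R ≤ r ≤ R + 1.0 Å, optionally with a unit-well-depth 6-12
energy (atom pairs; disjoint from short contacts by construction);
structural segments — runs of one side's interface residues split at
dense-index gaps > 5; protrusion index — per atom, (V_sphere − n·20.1) /
(n·20.1) with n the heavy atoms inside a 10 Å sphere, averaged per
residue then per interface; planarity — RMSD of interface atoms from
their least-square plane, with interfaces of fewer than four residues
marked ignored. "Electrostatic interactions" has no canonical geometric
definition; the implementation counts charged side-chain N/O pairs ≤ 6 Å
and is labelled as this package's own convention.

**DSI/NDSI split.** The swapped-domain interface (DSI) comprises contacts
in which either residue lies in (or within a ±1-residue margin of) a
crossing block — i.e. contacts involving an exchanged segment, in either
direction. The remainder (body–body contacts) is the NDSI. The concepts
come from the source method; this residue-assignment rule is this
package's, and the margin is configurable. Feature vectors are
normalised by interface area before the paired t-test
(`scipy.stats.ttest_rel`; zero difference variance is flagged degenerate
rather than given a p-value).

## Propensity statistics

P(i,s) = (n_is/N_s)/(n_i/N); the frequency-weighted mean Σᵢ P(i,s)·(nᵢ/N)
is identically 1 and is verified to 10⁻¹² in tests. Context counts can be
supplied directly or derived with a deliberately simple torsion-region
helix/sheet/loop assigner (`assign_secondary_structure`); external
assignments are accepted as columns. ln(f_h/f_l) uses the natural log and
refuses zero counts rather than smoothing them silently. A published
20×4 reference propensity matrix ships with the package; recomputing its
hinge-column correlations gives −0.504, −0.385, +0.610 against helix,
sheet and loop — consistent with the printed −0.51/−0.38/0.61 to within
one unit in the printed last digit, the precision the rounded matrix
supports.

## Synthetic-data generator

The generator emulates the geometry of domain swapping, not its
energetics. A protomer is a poly-backbone chain (N, CA, C, O, Cβ; ideal
Engh–Huber-like bond lengths and angles, trans ω) built by
natural-extension chaining from per-residue torsions: an α-helical body,
a hinge, and the swap segment as an extended strand. The **open** form
has the hinge extended in Q1; the **closed** (monomer) form switches the
hinge to a folded recipe in Q4 that packs the strand back against the
body antiparallel (fold recipes per hinge length 1–5 were fixed once by
a grid search maximising fold-back at a 6–12 Å lateral offset while
keeping the protomer slab-flat, since a bulging fold makes translated
side-by-side copies inseparable by a single plane).

The `orientation_change` knob (degrees) is honoured literally: the
closed-form hinge torsions are interpolated between the open recipe and
the full fold, solving for the interpolation factor whose *measured*
swap-tail reorientation matches the request (consecutive torsion changes
partly cancel, so the raw torsion offset is not a faithful angle). The
interpolation never drops below the floor at which every hinge residue's
(φ,ψ) differs between the forms by ≥ 40° — the generator's contract is a
conformational difference clearly above the 20° detection threshold, and
the 0.05 Å default coordinate jitter translates to ~7° of Δ(φ,ψ) noise,
so the design point sits ≈3σ above it.

A swapped dimer is the open protomer plus its exact two-fold image about
an axis n̂ chosen with Δ·n̂ = −d (Δ the body→swap centroid vector, d the
9 Å dock distance, n̂ tilted out of the body/swap plane): the image's
body then docks d beside the swap segment and the image's swap segment
docks d against the *opposite* face of the body, so each chain crosses
the partner's interface plane with the swap segment as the crossing
block. A side-by-side dimer is two closed protomers related by a pure
translation along the protomer's flattest principal direction, docked at
a 4.5 Å surface gap, on the face away from the hinge-loop bulge. The
trimer adds a closed protomer presented flat-face against the free face
of chain A's body. Placement noise (a rigid wobble of the partner, up to
10° in tests) and Gaussian coordinate jitter are seeded; fixed seeds give
bit-identical structures, and every oligomer is returned with its
ground-truth swap segment and hinge interval.

What the fixtures do **not** emulate: side chains beyond Cβ (except via
the explicit micro-fixture helper used in feature tests), realistic
packing density, sequence–structure consistency, crystallographic
artefacts (altlocs, missing density, symmetry mates) beyond what the
reader tests construct. Passing fixture tests therefore demonstrates the
correctness of the geometric logic under controlled conditions, not
classifier performance on borderline real structures.

## Numerical choices and degenerate inputs

Plane fits require ≥ 3 non-collinear points; Kabsch requires ≥ 3 pairs
and always returns a proper rotation. Dihedrals are undefined at
termini, at missing backbone atoms, and across chain breaks (C–N > 2.5
Å); undefined Δ values propagate and are never compared to thresholds.
Angle wrapping maps differences into (−180°, 180°]. SASA is
deterministic for a fixed sphere-point count. Resolution filtering
treats structures without a recorded resolution as a distinct rejection
class. Altlocs resolve to highest occupancy (first on ties); only the
first model of multi-model files is used, as the method is
crystal-structure based; MSE-type modified residues map to their parent
for statistics while remaining in the geometry.

## Known limitations

The plane criterion can be genuinely ambiguous for strongly curved or
interlocking non-swapped assemblies, and for higher oligomers a chain's
swap segment directed at a *third* chain can cross a pairwise interface
plane; the method inherits these properties from its geometric
definition. Hinge recovery degrades when the swap-domain reorientation
approaches the Δ threshold (small-reorientation swaps), and the
percent-identity homologue ranking ignores structural quality. The
H-bond and protrusion implementations are geometric approximations of
the programs historically used for these features, and interface areas
from a backbone-plus-Cβ model underestimate those of full-atom
structures.
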