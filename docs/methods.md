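# Methods

## Elastic network models

Both networks take one node per Cα and a single spring constant γ for all
node pairs within a distance cutoff (closed ball, d ≤ r_c). The GNM works
with the N×N Kirchhoff matrix Γ (graph Laplacian weighted by γ), the ANM
with the 3N×3N Hessian of the pairwise harmonic potential. Both are
decomposed with a full dense symmetric eigensolver (`scipy.linalg.eigh`);
the rings considered stay below ~1,700 nodes (ANM ≤ ~5,100 dof), where
exact decomposition costs seconds and avoids the convergence and gauge
ambiguities of iterative solvers. Zero modes are identified scale-freely
as λ < 1e-9·λ_max; a connected network must yield exactly 1 (GNM) or
6 (ANM) of them, and the ANM's rigid translations are verified to lie in
the numerical null space. Nonzero modes are indexed from 1 starting at the
slowest; all fluctuation amplitudes are in arbitrary units of 1/γ (k_BT
absorbed), so only relative and normalized quantities are reported.

Default cutoffs are r_c = 10 Å (GNM) and 15 Å (ANM) — the community
standard for Cα networks — and are parameters everywhere. γ = 1.

Verification uses two independent routes: the Moore–Penrose pseudoinverse
of Γ (mode-sum MSF and correlation maps must match its diagonal and its
normalized form to 1e-8) and, externally, the `bio3d` R package, whose GNM
fluctuations on the same structure and cutoff agree with ours up to the
global 1/γ scale to machine precision.

## Degenerate modes and gauge invariance

Cn symmetry forces the spectrum into non-degenerate (azimuthal wavenumber
m = 0, and m = n/2 for even n) and doubly-degenerate (m ≥ 1) levels. Within
a degenerate pair the eigenvector basis is arbitrary (solver-dependent), so
no reported quantity is computed from an individual pair eigenvector:
MSF and cross-correlation of a pair use M = Σ λ⁻¹uuᵀ over the pair, which
is (up to λ) the projector onto the 2D eigen-subspace and hence
basis-invariant; classification scores project templates onto the centered
subspace. Tests verify invariance under random orthogonal remixing of pair
eigenvectors, including reflections.

Grouping scans the slowest `n_consider` (default 5) nonzero modes and joins
consecutive modes when (λ_{k+1}−λ_k)/λ_k ≤ rel_tol. The default
rel_tol = 0.02 accommodates experimentally imperfect rings, where symmetry
breaking splits ideal pairs by ~0.5–2% (measured on the generator at
0.3 Å coordinate noise); noise-free rings are paired to 1e-9. Runs longer
than two modes (possible when distinct levels approach within the
tolerance) are split at their largest internal relative gap — for exact
ties this keeps the first gap, a deterministic convention.

## Motion-type classification

Each slow group's GNM scalar pattern is compared against three template
fields in cylindrical coordinates about the fitted axis (θ azimuth, z
axial, s(z) = ±1 for the two membrane halves):

* type I — cos(θ−φ): one half of the ring anticorrelated with the other;
  requires a degenerate pair (the two φ-phases span the subspace);
* type II — s(z): the top (loop-side, stromal) half against the bottom
  (luminal) half; requires a singleton;
* type III — cos(θ−φ)·s(z): four alternating blocks; requires a pair.

The score is the maximum |Pearson correlation| between the template
(φ swept on a 1° grid) and any unit vector of the group's centered
eigen-subspace; the best size-compatible template wins if its score
reaches `corr_threshold` (default 0.6), otherwise the group is labelled
"other". On noise-free generated rings the winning scores are ≈ 1.00 (I),
0.88 (II) and 0.88 (III), and 100/100 random patterns score < 0.6, so the
threshold sits in a wide margin between signal and noise. The split plane
for s(z) is placed at the axial position of the global minimum of the
folded MSF over the considered slow modes — the dynamic waist, which on
generated rings lands within a few Å of the inner-helix kink level.

Mode *rank* is never part of a contract: which type is slowest may differ
between rings; only the (group → type) assignment is asserted.

## Hinges

Hinges are detected on the symmetry-folded (monomer-averaged) MSF profile
of each group: positions at or below the `hinge_quantile` (default 0.2)
profile quantile are merged into runs, single-position gaps are bridged,
and runs shorter than `min_run` (default 3) are dropped. The quantile and
run length make "low mobility" explicit and reproducible; a flat profile
yields no hinges. On generated rings the type II/III hinge intervals
bracket both helix kink positions — parameter recovery of the generator's
ground truth.

## GNM↔ANM association

ANM modes are associated to a GNM group by Pearson correlation between
cross-correlation maps over the strict upper triangle; all candidates
within 0.05 of the best similarity are returned, since one scalar motion
class can correspond to several directional modes. A caveat specific to
*exact* Cn rings: an ANM mode's map inherits a cos(Δθ) factor from the
rotation of the local displacement frames around the ring, so the
torsional (twist) ANM mode's map equals s_i s_j cos(θ_i−θ_j) — identical
to the *type III* GNM map and exactly uncorrelated with the block-only
type II map. Map-based matching therefore discriminates cleanly for type I
(margin ≈ 0.8 on the generated 14-mer) but cannot uniquely pair the type
II group on an ideal ring; on real, imperfect rings the degeneracy is
lifted. The matching function is deliberately kept to its defined
semantics, and the type-I margin is what tests assert.

## Synthetic ring generator

The generator emulates the architecture of rotary-ATPase c-rings: n
identical hairpin monomers, each an inner helix (TM1, default 38 residues)
rising from the luminal face, a 4-residue stromal loop, and an outer helix
(TM2, 30 residues) descending; monomer 0 is replicated by exact z-rotations
so noise-free rings are Cn-symmetric to machine precision. Helices are
ideal α-helices (1.5 Å rise, 100°/residue, 2.3 Å backbone radius) wound
along an axis of two straight segments meeting at the kink angle (defaults
31°/20°), with the kink vertex displaced radially inward — producing the
mid-membrane waist of real c-rings, with the narrowest Cα position
adjacent to the TM1 kink.

Radial anchoring, deliberately asymmetric:

* `inner_radius` (17.5 Å) anchors the **TM1 axis at its kink vertex** —
  the waist, the functionally defining level of the pore;
* `outer_radius` (30 Å) anchors the **TM2 axis at its ends**, so a
  noise-free ring's measured outer diameter is 2·(outer_radius +
  helix_radius).

This choice packs the two helix walls against each other along their whole
length (axis gap ≈ 4–9 Å), as in real c-rings. It matters dynamically: if
instead both axes are end-anchored at the default radii, the walls sit
~12.5 Å apart, barely couple at the 10 Å GNM cutoff, and the slowest modes
become relative motions of two concentric rings (inter-wall torsion, m = 2
ovalization) rather than the hairpin-unit motions seen in real rings. With
the waist-anchored wall the generated 14-mer reproduces the canonical slow
spectrum — degenerate pair (I), singleton (II), degenerate pair (III) — at
the default cutoffs.

For ring sizes other than the 14-mer reference both radii shift by
(n−14)·inner_radius/14, keeping the azimuthal monomer spacing at the waist
constant (~8 Å): wall thickness is monomer-intrinsic while circumference
grows with subunit count, as across real c-ring stoichiometries. Optional
isotropic Gaussian coordinate noise (seeded, default 0) models imperfect
experimental symmetry; it is applied after replication so it breaks the
degeneracies it is meant to test.

What the generator does **not** emulate: side chains and sequence (residue
names default to ALA, with an optional GLU marker), super-helical wrapping
of the helices, termini tails, membrane or solvent. Tests passing on
generated rings therefore demonstrate the machinery's correctness on
ring-topology inputs with known ground truth, not agreement with any
particular crystal structure; deposited-structure checks are separate and
require the user to supply the PDB file.

## Ring geometry conventions

Diameters are Cα-to-axis based (twice the per-position mean radial
distance over the n symmetry copies), not surface based — reproducible
without atom radii; comparisons against surface-convention numbers carry
±2 Å tolerances. The symmetry axis is the gyration-tensor eigenvector
minimizing the RMSD of the coordinate set under a 2π/n rotation
(minimized over rotation sense and cyclic monomer correspondence); a
best score above 5 Å RMSD, or collinear input, is rejected as "not
ring-like". The axis sign puts the chain-midpoint centroid (the loop side
of a hairpin ring) at +z. End diameters are measured in top/bottom axial
slabs of 15% of the height.

Kink angles come from a two-segment principal-axis fit with the kink
residue excluded. The Cα trace winds about the helix axis with a
~3.6-residue period, which tilts a plain principal-axis fit of short
segments by up to ~4°; the trace is therefore smoothed with a one-turn
(4-residue) moving average before the fit, bringing recovery of
constructed kinks to within 1° and straight-helix readings below 0.5°.

The hydropathy profile bins lipid-facing residues (outer half of each
z-bin's radial distribution) in 2 Å slabs; bins left empty by the discrete
Cα spacing are bridged by linear interpolation. The hydrophobic core is
the longest run of bins above the scale's neutral point. The default scale
is Kyte–Doolittle (neutral 0); `HYDROPATHY_SCALES` is an open registry, so
a transfer-free-energy scale can be added (negate values so hydrophobic is
positive) and selected by name.

## Pipeline determinism and sizes

`run_full_analysis` is deterministic for a fixed configuration — reports
contain a config hash and no timestamps, and identical configs produce
byte-identical JSON. The test suite and the acceptance script run entirely
on generated rings: the default 14-mer (1,008 nodes; GNM ~1.5 s, ANM ~9 s
on one core), a 96-node 6-mer for oracle-grade comparisons, a 200-node
8-mer for pipeline-level tests, and the 8–15 sweep with full-size monomers
(GNM only, ~5 s total). These sizes were chosen to exercise every code
path at full monomer resolution while keeping a complete run under a
minute.

## Known limitations

* No mass weighting, distance-dependent force constants, or solvent/
  membrane damping: the analysis is of the undamped network, and mode
  amplitudes are in arbitrary units.
* Map-based GNM↔ANM matching is non-identifiable for the twist class on
  exactly symmetric rings (see above).
* The hinge-plane estimate assumes the folded-MSF minimum marks the
  mid-membrane belt; for non-hairpin monomers (e.g. four-helix V-type
  subunits) the split may need to be supplied explicitly.
* `read_calpha_pdb` reads fixed-column PDB only; mmCIF is out of scope.
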