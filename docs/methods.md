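# Methods

This note documents the models, conventions and numerical choices behind
`lnbuild`, in the order the build pipeline uses them.

## Molecular model

A molecular system is (atom list, topology function τ, geometry matrix X in
Å). τ maps unordered atom pairs to the bond orders {0, 1, 1.5, 2, 3};
aromatic/delocalized bonds are stored as 1.5, coordination bonds as 1.
Topology is always explicit — the package never perceives bonds from
coordinates, because every downstream decision (torsion freezing, color
equivalence, tooth identification) is topological.

**Cycles and free torsions.** Ring perception uses a cycle basis of the bond
graph; the only property consumed downstream is *membership* (every atom and
bond on any simple cycle appears in the basis, which the tests verify
against exhaustive cycle enumeration on small graphs). A free torsion is a
proper dihedral (externals exist on both sides, lowest-serial convention)
whose internal bond is not on a ring. Rotating a torsion moves the smaller
connected half across the internal bond (ties go to the i2 side, for
determinism); the rotation axis passes through the first internal atom, so
rotating about it preserves all bond lengths exactly — a rotation about the
coordinate origin would not. The axis-to-z factorized rotation matrix has a
removable singularity when the axis is parallel to z; identity factors with
the sign of w handle it.

## Colors, ligand order, formula

Tooth colors are computed by Weisfeiler–Lehman refinement over the disjoint
union of all ligand graphs (initial label = element; iterate
neighborhood-multiset hashing with canonical class renaming until the
partition stabilizes). Equal colors therefore mean indistinguishable rooted
environments of element + bond order, the recursive equivalence the color
concept demands; formal charges are not encoded (colors follow atoms and
bonds only). Colors are numbered by sorted class signature, hence invariant
under atom re-serialization.

Ligands are ordered by (denticity ascending; identically-colored teeth
descending; ligand-type multiplicity descending; lowest color ascending;
full type). The multiplicity key keeps the internal tooth order aligned
with the generic-formula notation (in Ma3b(AB)2 the letter *a* is the
three-fold ligand), which the permutation encoding of stereoisomers relies
on. The complex geometry is the metal row (fixed at the origin) followed by
the ligand blocks in this order; global/local index maps add the +1 metal
offset to the block-relative index.

## Bond-length tables

Target coordinate bond lengths (pm) are tabulated per (lanthanoid,
oxidation state, coordinating element); they represent median + MAD
distances over curated crystal structures — deliberately looser than the
median so downstream optimizers compress rather than untangle. Pairs absent
from the tables are filled by the ionic-radius shift rule
r₀[N,t] = r₀[M,t] − ϱ[M] + ϱ[N] with argument ions Eu³⁺ (O, N, S, Cl, Br),
Dy³⁺ (P, I), Pm³⁺ (F) and Eu²⁺ for all divalent entries. Divalent radii
missing from the literature come from the quadratic fit
ϱ(Z) = 0.2097 Z² − 30.043 Z + 1177.2 (R² = 0.995 over the six literature
divalent radii). Stored values are integer pm (half-up rounding);
interpolation validates stored entries to ±1 pm. One correction: the
trivalent Er radius is shipped as 89.0 pm — the 98.0 pm value sometimes
printed is inconsistent both with the strict La→Lu contraction and with the
F-column interpolation, which reproduces every fluorine entry to ±1 pm only
with ≈89 pm. Note that database-derived entries themselves are not
monotonic across the series (e.g. the Cl and Br columns); only interpolated
entries inherit the monotone radii.

## Reference polyhedra

The shape library (packaged JSON, regenerated by
`scripts/make_shape_library.py`) holds idealized vertex coordinates with a
documented orientation and numbering for twelve shapes: T-4, TBPY-5, SPY-5,
OC-6, COC-7, PBPY-7, SAPR-8, TDD-8, BTPR-8, TCTPR-9, MFF-9, JBCSAPR-10.
Constructions worth noting:

- **OC-6** is numbered (+x, +y, +z, −y, −z, −x) so the antipodal index
  pairs are (1,6), (2,4), (3,5): consecutive index pairs are then edges,
  which keeps the classical tris-chelate permutations [1 2 3 4 5 6] and
  [1 2 5 4 3 6] valid (both D3, an enantiomeric pair).
- **BTPR-8** is the Johnson solid J50 (unit edge, vertex centroid at the
  origin), *not* radially projected onto the sphere: projection would fold
  the remaining planar square face and add a spurious edge.
- **MFF-9** (muffin, Cs) is an apical cap, a 5-ring at 75° inclination and
  a 3-ring at 138°, one vertex of each ring on the cap's mirror plane.
- **SAPR-8** and **JBCSAPR-10** use the sphere-inscribed square antiprism
  with the ring inclination that equalizes intra- and inter-ring edges.

**Bite pairs** — the vertex pairs a bidentate may span — are the true
convex-hull edges (simplex edges whose adjacent facets are non-coplanar, so
triangulation diagonals of planar faces are excluded). A nearest-neighbor
criterion with a 1.2× minimal-edge factor was considered and rejected: it
would drop the polar–equatorial edges of the pentagonal bipyramid (ratio
1.203). The hull-edge convention is validated by two published censuses it
reproduces exactly: 640 stereoisomers (12 achiral) for Ma3b(AB)2 on BTPR-8
and 232 (10 achiral) for Ma3(AA)3 on MFF-9. These censuses are sensitive to
both the edge set and the rotation group, so they pin the conventions
tightly; the muffin census is additionally insensitive to the ring
inclinations over ±15°, so the chosen angles are cosmetic.

**Rotation groups** are detected numerically: candidate vertex bijections
are grown by backtracking on pairwise-distance compatibility and accepted
when an exactly orthogonal matrix (from the SVD of the covariance, det +1)
realizes them within 1e-5; group closure is asserted. Improper isometries
(det −1) are detected the same way and used for combinatorial achirality
tests and Schoenflies labels of placements.

## Stereoisomer enumeration

A placement assigns each vertex a tooth label and groups bidentate teeth
into pairs; asymmetric bidentates are directed, symmetric ones undirected,
identical ligands indistinguishable by construction of the serialized form.
Stereoisomers are orbits of placements under the proper rotation group; the
canonical representative is the lexicographically least serialization in
the orbit, converted to a vertex permutation (1-based bracketed text
externally). Counting uses explicit orbit enumeration, except for
monodentate-only formulas where Burnside's lemma applies (a cycle-type
dynamic program; for all-distinct labels only the identity fixes any
labeling, giving n!/|G| directly). Enumeration and Burnside agree on every
mixed case tested. Enumeration covers mono- and bidentate ligands;
tridentate-and-up placements are out of scope.

A built structure's stereoisomer is re-identified by optimally assigning
teeth to reference-shape vertices by angular distance (Hungarian method)
and canonicalizing; fixed-shape builds assert the result equals the request
and fail hard on drift.

## Chirality

Verdicts use stochastic mirror pairing: mirror the teeth (negate x — any
fixed reflection is equivalent up to rotation), apply a uniform random
rotation (unit quaternion from the seeded generator), pair mirrored and
original teeth by the Hungarian method on a cost of distance × 1e10^(
precedence mismatch), superpose with the Kearsley quaternion fit and test
the RMSD against the threshold (default 0.14 Å, configurable): below it at
any iteration → achiral; never below in 10 000 iterations → chiral. Tooth
radii are normalized to the unit sphere first so the threshold behaves
consistently across bond-length scales; the raw-coordinate behavior is
available via `normalize=False`. One or two teeth are achiral by
construction (always coplanar with the metal). The seed is recorded in the
verdict. Note the method sees only positions and precedences: a chelate's
connectivity enters indirectly, through the geometric twist it imposes —
e.g. a tris-chelate's propeller twist away from the ideal octahedron is
what makes its equal-precedence polyhedron chiral.

## Geometry initialization

*Free shape*: ligand barycenters go to the first |𝓛| points of the
farthest-point-ordered spherical Fibonacci lattice (N = 30, i.e. 31
points; x = frac(n/φ), y = n/N; azimuth 2πx, inclination arccos(1−2y)),
each at radius (mean tooth r₀) + |barycenter − teeth centroid| with teeth
oriented toward the metal.

*Fixed shape*: sites come from the stereoisomer permutation's consecutive
tooth blocks; vertices are rescaled to r₀ along their unit directions
(idempotent). Each ligand's effective teeth set (teeth + reference point =
centroid of the teeth's bonded neighbors) is Kearsley-superposed onto its
effective site (vertices + site centroid scaled by d = 1.7); the rotation
comes from that fit but the translation matches the teeth centroid to the
site centroid exactly — the raw fit would shift teeth along the axis
whenever the ligand's reference distance differs from the site's, a
residual no wheel/hinge angle could repair. Monoatomic ligands have no
qualifying neighbors; a fabricated reference point behind the tooth is used
and flagged (the spin is irrelevant for a spherical ion).

## Optimization

Crowding Ξ = S + αW is minimized with scipy's trust-region solver
(`trust-constr`) over the active degrees of freedom, with central-difference
gradients. Fixed-shape mode varies free torsions and wheel/hinge angles
(teeth are tethered by the vertex-form warp); free-shape mode varies free
torsions, Euler angles (Z-Y-Z, about the ligand barycenter) and
coordination-space positions (spherical barycenter coordinates), with the
radial-form warp. Ray and space positions are mutually exclusive by
construction of the DOF vector. S includes *every* unique atom pair — metal,
bonded and intra-ligand pairs — so torsions feel intra-ligand tension; atom
pairs closer than 1e-6 Å raise a singularity error naming the pair.

Free-shape builds run a staged schedule: a rigid-ligand angular
pre-relaxation (only each barycenter's inclination/azimuth vary, the ligand
co-rotating at fixed radius) precedes the full-dimensional run. The lattice
seed for small ligand counts is near saddle-like arrangements (e.g.
square-planar-ish for four ligands) where a purely local full-DOF
minimization can stall ~10° from the repulsive optimum; the staged schedule
reaches the linear/trigonal/tetrahedral basins (within ~3° for 2–4
identical monodentates) and a lower objective.

Convergence is declared when the objective decrease stays below
1e-4 Å⁻¹ for three consecutive iterations (minimum five) — the first
trust-region iterations can make near-zero progress while the radius
adapts — or at the iteration cap. Accepted-step objectives are
non-increasing; the best-seen vector is applied at exit.

## Problem sizes and what the tests show

The test fixtures are small idealized ligands (water, ammonia, chloride,
nitrate, nitrite, acetylacetonate, a synthetic asymmetric O,O-chelator
standing in for vanillinate, 2,2'-bipyridine) on complexes of 3–40 atoms,
chosen so the full suite exercises every pipeline stage — enumeration up to
coordination number 10, fixed-shape builds on OC-6/MFF-9/BTPR-8, free-shape
builds of 2–6 ligands — in well under a minute. The generator emulates
correct topology, denticity and idealized geometry; it does not emulate
conformational diversity, real bite-angle strain, charge effects or bulky
substituents, so passing tests demonstrate correctness of the
stereochemical machinery and the qualitative behavior of the objective, not
agreement with experimental geometries — which the method, being purely
repulsive, deliberately does not target: its outputs are starting
structures for higher-level model chemistries.

## Known limitations

- Stereoisomer enumeration covers mono- and bidentate ligands; higher
  denticities assemble and optimize but cannot be enumerated or encoded.
- Crowding has no attractive or electrostatic terms; ligand charge is
  metadata only.
- Optimization is local; distinct free torsional minima are not searched.
- Fixed-shape mode never relaxes tooth positions freely (the warp tether is
  the only slack); an explicit switch for tooth relaxation is not exposed.
- The chirality verdict is stochastic: "chiral" is certified only up to the
  iteration budget, though 10 000 iterations is far beyond what the tested
  polyhedra need.
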