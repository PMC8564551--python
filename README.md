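# lnbuild

Stereochemically controlled starting structures for metal coordination
complexes — primarily lanthanoids, whose coordination numbers of 6–12 produce
a combinatorial explosion of stereoisomers that standard structure builders
ignore.

A lanthanoid complex of a given formula and coordination-polyhedron shape is
usually not one structure but one of dozens to hundreds of thousands of
distinct stereoisomers, many of them chiral. `lnbuild` is for computational
and coordination chemists who need, as input to molecular-mechanics or
quantum-chemical optimizations, either one specific stereoisomer or the
complete non-redundant set: it enumerates the stereoisomers of a shape,
builds the requested one, recognizes coordination chirality, and relaxes the
geometry so the ligands do not choke one another.

## The model

**Stereoisomers as orbits.** A complex with generic formula such as
Ma3(AA)3 (three monodentate ligands *a*, three symmetric bidentates (AA)) on
a shape with vertex matrix **Z** is encoded as a permutation of the vertex
rows: tooth *k* sits on vertex *perm[k]*. Two permutations are the same
stereoisomer when a proper rotation of the polyhedron maps one tooth
placement onto the other, so distinct stereoisomers are orbits of valid
placements (bidentate teeth restricted to polyhedron edges) under the
rotation group. For all-different monodentate ligands the count is
*n*!/|G| — 2 on the tetrahedron, 30 on the octahedron, 5040 on the square
antiprism, 453 600 on the bicapped square antiprism.

**Crowding.** Geometries are produced by minimizing the crowding

&nbsp;&nbsp;&nbsp;&nbsp;Ξ = S + α·W,&nbsp;&nbsp;&nbsp; α = 100·|𝒜|/√|Π| (Å⁻³),

where the steric congestion S = Σ w/r over every unique atom pair (weights
4, 2, 1 for heavy–heavy, heavy–H, H–H) is purely repulsive and spreads the
ligands out, and the coordination warp W tethers the teeth — to the rescaled
shape vertices (fixed-shape builds) or to tabulated target bond lengths
(free-shape builds). Target metal–tooth distances are median + MAD values
per (lanthanoid, oxidation state, coordinating element), completed across
the series by the ionic-radius shift rule
r₀[N,t] = r₀[M,t] − ϱ[M] + ϱ[N]. The minimization runs over the ligands'
degrees of freedom only: free torsions, wheel/hinge angles, barycenter Euler
angles and positions.

**Coordination chirality.** The polyhedron (teeth + CIP-style precedence
integers) is mirrored, randomly reoriented, optimally paired with the
original by the Hungarian method on a precedence-penalized distance cost,
and superposed with the Kearsley quaternion fit; if the RMSD ever drops
below 0.14 Å the arrangement is achiral, and chiral if it survives 10 000
iterations.

## Worked example

Triaquatrinitro-lutetium(III), Lu(NO₃)₃(H₂O)₃, generic formula Ma3(AA)3, on
the muffin shape (MFF-9). How many stereoisomers exist?

```
$ lnbuild enumerate --shape MFF-9 --formula "Ma3(AA)3"
232
```

232 distinct stereoisomers (of which 222 are chiral and 10 achiral — see
`lnbuild enumerate --list` and the chirality classifier). Build one of them:

```
$ lnbuild build --metal Lu --ligand water=3 --ligand nitrate=3 \
      --shape MFF-9 --isomer "[1 6 7 2 3 4 5 8 9]" --seed 1 --out lu.xyz
formula: Lua3(AA)3
stereoisomer: [1 6 7 2 3 4 5 8 9]
chiral: False
crowding Xi: 590.8802
converged: True
```

The reported stereoisomer is re-identified from the *output* geometry — the
build fails loudly if optimization ever drifted to a different isomer. This
particular permutation is one of the ten achiral ones (`chiral: False`); the
final crowding Ξ = 590.88 Å⁻¹ is the converged objective (congestion plus
weighted warp) for the 22-atom structure written to `lu.xyz`, with the metal
on the first line at the origin.

The library API mirrors the CLI: `lnbuild.shapes.enumerate_stereoisomers`,
`lnbuild.assemble.build`, `lnbuild.chirality.is_chiral`,
`lnbuild.bondtables.BondTargetTable` and friends.

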