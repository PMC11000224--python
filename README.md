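# mconiom

Multicenter *n*-layer subtractive ONIOM with mechanical embedding, as a
reusable Python library and CLI: tree-structured fragment partitioning,
hydrogen link-atom capping, recursive assembly of composite energies,
gradients and Hessians with Jacobian projection, and mRRHO
thermochemistry for supramolecular reaction free energies and their
temperature dependence.

## The problem

Reactions buried inside large (bio)molecules — the textbook case being
disulfide bridges inside a cysteine-rich protein — need quantum-chemical
accuracy locally but are far too large for a high-level method globally.
Subtractive ONIOM schemes solve this by combining levels of theory:

```
E = E_low(real) + E_high(model) − E_low(model)
```

where *real* is the full system and *model* a capped fragment around the
chemically active region. This package generalises the two-level formula
to an arbitrary **dependency tree** of fragments: layer 1 is a single
root node holding every atom, deeper layers hold disjoint fragments
("centers"), each a strict subset of its parent, and the composite
property of a node is assembled recursively,

```
F_i = HIGH_i(model_i) + Σ_j∈children(i) [ F_j − LOW_j(model_j) ]
```

with each node's low level equal to its parent's high level. Bonds cut
by a fragment boundary are saturated by a hydrogen link atom placed
statically on the cut bond a→b,

```
r_l = r_a + k_ab (r_b − r_a),     k_ab = (R_a + R_H) / (R_a + R_b)
```

using single-bond covalent radii R. Because the cap position is an
affine combination of real-atom positions, the real→model coordinate map
is linear; its sparse Jacobian **J** (3×3 blocks: identity for fragment
atoms, (1−k)·E and k·E for the two hosts of each cap) pulls fragment
gradients and Hessians back to the real basis as Jᵀg and JᵀHJ. The
composite Hessian feeds a modified rigid-rotor-harmonic-oscillator
(mRRHO) free energy in which low-frequency vibrational entropies are
interpolated toward a free-rotor limit with weight
`w(ν) = 1/(1+(ν₀/ν)⁴)`, ν₀ = 25 cm⁻¹, keeping G(T) stable for floppy
systems.

Embedding is purely mechanical: layers couple through geometry and the
subtractive energy expression only, never through electrostatics.

The package ships analytic toy potentials (a transferable harmonic force
field and a dissociative Gaussian-bond force field) behind the same
calculator contract used for external engines, so the entire multiscale
machinery runs and is testable without any quantum-chemistry download.

## Worked example

Generate the three-bridge toy fixture — a 40-atom chain with three
disjoint S–S "disulfide" pairs, partitioned into 1 root + 3 middle +
3 inner nodes across three levels of theory (`ff`, `sqm`, `dft` toy
calculators of increasing stiffness):

```sh
$ mconiom fixtures --kind tri_bridge_peptide --seed 13 --out fx
$ mconiom energy -g fx/geometry.xyz -p fx/partition.toml --calc-file fx/calculators.toml
INFO node root     high=+0.01941365 Eh  low_correction=+0.00000000 Eh
INFO node mid1     high=+0.00365341 Eh  low_correction=-0.00286223 Eh
INFO node ss1      high=+0.00152493 Eh  low_correction=-0.00104608 Eh
...
composite energy  +0.0270453136 Hartree  (+16.9712 kcal/mol)
```

Each line is one fragment evaluation: the node's high-level energy and
the subtractive low-level correction; their signed sum is the composite
energy. Optimising a smaller one-bridge dimer and running
thermochemistry on its assembled composite Hessian:

```sh
$ mconiom fixtures --kind bridge_dimer --seed 13 --out bd
$ mconiom opt -g bd/geometry.xyz -p bd/partition.toml --calc-file bd/calculators.toml \
      --gtol 1e-6 --xyz-out bd/opt.xyz
converged after 36 iterations; E = +0.0000256583 Hartree, max |g| = 7.54e-07
$ mconiom thermo -g bd/opt.xyz -p bd/partition.toml --calc-file bd/calculators.toml
T                       298.15 K
E(elec)                 0.0161 kcal/mol
ZPE                     6.2995 kcal/mol
U(vib)                  2.5267 kcal/mol
S(vib)                 26.4682 cal/mol/K
S(rot)                 27.1201 cal/mol/K
S(trans)               40.0602 cal/mol/K
H                      11.2122 kcal/mol
G                     -16.7091 kcal/mol
imaginary modes              0
```

The Gibbs energy combines the composite electronic energy, harmonic ZPE
and thermal terms, Sackur–Tetrode translation, rigid-rotor rotation, and
the interpolated vibrational entropy. `mconiom scan` evaluates reaction
ΔG(T) over a temperature grid from the same composite-Hessian route, and
the library API (`mconiom.composite`, `mconiom.optimize`,
`mconiom.normal_modes`, `mconiom.mrrho_gibbs`, `mconiom.reaction_delta`)
exposes every step programmatically.

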