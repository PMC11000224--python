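# Methods

## Model

The package implements a subtractive multicenter *n*-layer ONIOM scheme
with mechanical embedding. A partition of the real system is a rooted
tree: the root (layer 1) contains every atom; every other node is a
strict subset of its parent, siblings under one parent are pairwise
disjoint, and a node's layer is its parent's plus one. Each node carries
a high level of theory (its own calculator); its low level is, by
construction, the parent's high level. The composite property (energy,
gradient or Hessian) of node *i* is assembled recursively,

    F_i = HIGH_i(model_i) + Σ_j∈children(i) [ F_j − LOW_j(model_j) ],

terminating at leaves with F = HIGH(model). With a single calculator
bound to every level the sum telescopes exactly to the plain calculation
on the real system; this identity is the scheme's defining property and
is enforced by the test suite at 1e-12 (energy), 1e-10 (gradient) and
1e-8 (Hessian).

Mechanical embedding means layers interact only through geometry and the
subtractive expression; no point charges or polarisation cross layer
boundaries. Per-node charge and spin labels are accepted and passed to
calculators untouched (the built-in toy potentials ignore them).

### Link atoms and Jacobians

A bond a–b cut by a fragment boundary (a inside, b outside) is saturated
by a hydrogen cap at

    r_l = r_a + k_ab (r_b − r_a),   k_ab = (R_a^cov + R_H^cov) / (R_a^cov + R_b^cov),

with single-bond covalent radii (Pyykkö–Atsumi values for Z ≤ 36 ship as
an explicit, overridable table; k can also be overridden per bond in the
partition config). k is static — no new degrees of freedom enter. The
real→model coordinate map is therefore linear; its Jacobian consists of
3×3 blocks that are scalar multiples of the identity: one unit block per
fragment atom, and the pair (1−k), k on the two hosts of each cap. Each
model atom's block scalars sum to one, which makes composite gradients
translation-consistent: the net force and net torque of the composite
gradient vanish whenever the underlying calculators are translation- and
rotation-invariant. Fragment gradients and Hessians are pulled into the
real basis as Jᵀg and JᵀHJ before accumulation, using the block
structure directly (dense matrices appear only in tests, as the oracle).

Model-system atom ordering is frozen: fragment atoms in ascending
real-index order, then caps in cut-bond order. Jacobian indexing depends
on this ordering. Two caps on the same host atom are permitted but
flagged with a warning (geometrically strained).

When no bond topology is supplied, bonds are inferred by the
conventional distance rule d < 1.15 · (R_a + R_b); the factor is a
module constant and topology can always be given explicitly.

### Calculators

All levels of theory sit behind one contract: `evaluate(geometry,
charge, uhf, wanted) → (E, g, H)`. Two analytic toy potentials ship:

* **HarmonicFF** — bond stretches ½k_b(r−r₀)², angle bends
  ½k_θ(θ−θ₀)², and weak 1–4 stretches ½k₁₄(r−r₁₄)². Equilibrium bond
  lengths are covalent-radius sums (scaled by `r0_scale`), the
  equilibrium angle is tetrahedral, and r₁₄ is the 1–4 distance of an
  ideal planar-trans path. Deriving all equilibria from element tables
  makes the potential transferable: the same calculator evaluates the
  real system and any hydrogen-capped fragment, which a per-geometry
  parameter dict cannot do. The 1–4 term exists because pure bond/angle
  force fields leave chain torsions with zero restoring force, which
  would produce spurious zero modes in every Hessian; with it, toy
  minima have clean positive spectra (long chains still develop
  genuinely soft torsional modes — the regime the mRRHO interpolation
  is designed for). Explicit per-term parameters remain available for
  closed-form test cases. Defaults: k_b = 0.35, k_θ = 0.15,
  k₁₄ = 0.02 (Hartree/Å² or Hartree/rad²), chosen to put stretch
  frequencies in the hundreds of cm⁻¹ for second-row elements.
* **DissociativeFF** — Gaussian wells −D·exp(−(r−r₀)²/2w²) on a fixed
  reference bond list plus Lennard-Jones terms on all non-bonded,
  non-1-3 pairs. Bonds dissociate monotonically to zero energy — bond
  cleavage has no barrier — and the reference topology is frozen at
  construction so broken bonds can re-form, mirroring dissociative
  force fields used for bond-breaking pathway studies. The energy is
  bounded below by −ΣD plus the LJ minimum sum.

Gradients are analytic; Hessians are central finite differences of the
analytic gradient (step 5e-4 Å), accurate to ~1e-7 in the elements —
sufficient for every tolerance used here and much simpler to audit than
analytic second derivatives of angle terms. `ShiftedCalculator`
(E′ = s·E + c) manufactures distinguishable levels of theory from one
base, and `ExternalCalculator` shells out to any engine speaking a small
JSON protocol (energy/gradient with declared units); it is optional and
never exercised by default beyond mock engines.

Within one composite evaluation, fragment results are memoised by
(level, charge, spin, elements, coordinate bytes): a node whose level
coincides with its parent's is evaluated once, not twice. The cache
never crosses calls, so it cannot affect values. Accumulation follows
the stored child order; results are independent of evaluation order.

### Geometry optimization

`optimize` wraps BFGS (scipy) over the composite energy/gradient with a
convergence criterion of max |g| < 1e-4 Hartree/Å by default, re-checked
on the final geometry independently of the optimizer's own report;
non-convergence returns the last geometry flagged rather than raising.

## Thermochemistry

Normal modes: the (composite) Hessian in Hartree/Å² is mass-weighted,
translations and rotations about the center of mass are projected out
(the basis of the projected space is obtained by SVD of the six
translation/rotation vectors — QR is unsafe here because the rotation
set is rank-deficient for linear molecules), and the projected matrix is
diagonalized. Negative eigenvalues are reported as negative frequencies.
Exactly 3N−6 (3N−5 linear) modes are returned; linearity is detected by
an inertia-eigenvalue ratio below 1e-6.

Free energies use the mRRHO model at 1 atm:

* translation: Sackur–Tetrode entropy, U = 3/2 RT;
* rotation: rigid rotor from the inertia tensor, symmetry number σ = 1
  by default (no point-group perception — a documented limitation);
* vibration: ZPE = Σ hν/2 over real modes; entropy per mode is the
  interpolation w·S_HO + (1−w)·S_FR with w(ν) = 1/(1+(ν₀/ν)^α),
  ν₀ = 25 cm⁻¹, α = 4, and the free-rotor entropy uses an effective
  moment μ′ = μB_av/(μ+B_av) with B_av = 1e-44 kg·m². ν₀, α and B_av
  are all arguments. The vibrational internal energy is interpolated
  with the same weights (free-rotor limit RT/2 per mode); without this
  the thermodynamic identity dG/dT = −S would be violated by the
  low-frequency modes. The identity is verified by finite differences
  to 1e-4 in the tests.

The smooth weight is applied to **all** modes (it is ≈1 above the
threshold); a hard HO/free-rotor switch at ν₀ is available via
`interpolate=False`. As ν → 0⁺ the free-rotor branch caps the entropy at
a finite value, which is what makes free energies of floppy systems
numerically stable — verified on a log grid over ν ∈ [0.1, 4000] cm⁻¹.

Imaginary modes are excluded from the vibrational sums, with a warning
for a declared minimum; a structure marked as a transition state may
carry exactly one silently. Modes below 1 cm⁻¹ in magnitude are treated
as projection remnants and dropped.

Reaction energetics follow the supramolecular approach: ΔX =
Σ products − Σ reactants with stoichiometry, after an element-balance
check (small molecules such as H₂ must be declared explicitly).
`temperature_scan` re-evaluates only the thermostatistical terms on a
temperature grid, reusing each species' frequencies.

### The composite-Hessian route

The scientifically load-bearing claim is that thermochemistry computed
from the *assembled* multiscale Hessian (recursion + JᵀHJ projection)
agrees with thermochemistry from a direct finite-difference Hessian of
the composite energy surface. The tests optimize toy fixtures to a
minimum (max |g| < 1e-6), run both routes, and require |ΔG(298.15 K)| <
0.05 kcal/mol; measured agreement is ~0.01 kcal/mol on the 5-atom chain
and 6-atom bridge-dimer fixtures.

## Synthetic fixtures

Fixtures are pure functions of (kind, seed): planar-trans zigzag chains
built exactly at the default HarmonicFF equilibrium, plus seeded
Gaussian jitter (σ = 0.03 Å) that breaks planarity. Kinds: `diatomic`
(zero-gradient start), `chain` (5 atoms, two layers), `bridge_dimer`
(6 atoms C-C-S-S-C-C, one bridge, two layers), and
`tri_bridge_peptide` — a 40-atom chain with N/O substitutions and three
disjoint S–S pairs, each wrapped by a 6-atom middle-layer fragment: a
toy-scale analogue of a three-disulfide protein, giving the canonical
1+3+3-node, three-layer, three-center tree. The three bundled toy
levels (`ff`, `sqm`, `dft`) are HarmonicFF variants of increasing
stiffness and slightly compressed equilibrium lengths, so the layers are
genuinely distinct surfaces.

What the fixtures do **not** emulate: real electronic structure (bond
polarisation, charge transfer, dispersion), conformational diversity,
and realistic frequency distributions. Passing tests therefore validate
the *bookkeeping mathematics* — partitioning, capping, projection,
assembly, thermostatistics — exactly, but say nothing about the accuracy
of any particular QM/SQM/MM combination on real molecules; those depend
entirely on the external calculators a user binds.

The bundled toy association reaction (2 N₂ → N₄ chain under HarmonicFF)
is electronically thermoneutral by construction (both sides sit at their
harmonic minima with E = 0), so its ΔG(T) isolates the thermostatistical
content: the loss of one molecule's translational/rotational entropy
makes ΔG positive and increasing in T (measured slope ≈ +0.033
kcal/mol/K over 200–400 K).

## Numerical choices

* Units: Å, Hartree, amu, cm⁻¹ internally; kcal/mol in reports
  (1 Hartree = 627.509474 kcal/mol).
* Atom indexing: 0-based in the API, 1-based in all files and messages.
* Finite-difference steps: 5e-4 Å (calculator Hessians), 1e-4 Å
  (gradient oracles), 5e-3 Å (second-order energy-only Hessian oracle —
  larger because the 4-point formula divides by h²).
* Composite Hessians are symmetrized ((H+Hᵀ)/2) after accumulation to
  suppress finite-difference asymmetry.
* Tree validation is a pure reporting pass (`validate_tree`); `build_tree`
  runs it and refuses invalid partitions with node-labelled messages.
* Problem sizes throughout tests and the acceptance script (2–40 atoms,
  ≤ 8 tree nodes, 800-point dissociation scans, 21-point temperature
  grids) were chosen so every check completes in seconds while still
  exercising multi-center, multi-layer recursion depth ≥ 3.

## Known limitations

* Mechanical embedding only; no electrostatic or polarisable embedding.
* No symmetry numbers beyond σ = 1, no conformational (landscape)
  entropy, no solvation model — single-structure gas-phase mRRHO only.
* The dissociative force field is a behavioural stand-in with Gaussian
  wells; it reproduces barrierless cleavage qualitatively, not any
  specific published force field's parameters.
* PDB input is a minimal coordinate/element reader; no residue
  chemistry, alt-locs or multi-model handling.
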