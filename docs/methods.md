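# Methods

This note records the modeling choices behind `gridmol`, their defaults,
and what the synthetic test fixtures do and do not establish.

## Atom typing

Atoms are typed by five properties concatenated in a fixed order: element
(one-hot over 11 symbols per role), aromaticity (one-hot false/true),
H-bond acceptor (indicator), H-bond donor (indicator), formal charge
(one-hot over −1/0/+1), for 18 channels per role. Ligand and receptor
element lists differ (B, C, N, O, F, P, S, Cl, Br, I, Fe vs. C, N, O, Na,
Mg, P, S, Cl, K, Ca, Zn) and the two roles are always gridded as separate
18-channel grids — the steric loss multiplies the two grids, so they must
be distinct tensors. Within a property, values keep their listed order;
the layout is serializable to JSON so alternative schemes are
configurable. Hydrogen is absent from both element lists: hydrogens are
stripped before typing and recovered by bond inference.

Aromaticity and formal charge are read from RDKit perception of the input
structure. Donor/acceptor roles use SMARTS definitions pinned in the
source (derived from the common Lipinski-style patterns, widened from
"exactly one H" to "at least one H" on oxygen so that water is both donor
and acceptor). `untype` inverts `type_atom` exactly on valid vectors
(argmax per one-hot block, 0.5 threshold on indicators); atoms missing a
charge annotation default to 0.

## Density grids

The kernel is the truncated Gaussian `f(d, r) = exp(−2 d²/r²)` for
`d ≤ c·r`, 0 beyond, with radius `r = 1.0 Å` for every atom and cutoff
multiplier `c = 1.5` (both configurable on `GridSpec`). It is 1 at the
atom center, monotone nonincreasing, and compactly supported — the
property that lets two structures 3 Å apart have *exactly* zero density
overlap, which the steric loss exploits. The default grid is a 23.5 Å
cube at 0.5 Å resolution; lattice points sit on both boundary faces
(fence-post: 47 intervals → 48 points per axis). Grids are centered on
the ligand's heavy-atom centroid before pose augmentation; receptor grids
share the ligand-derived center.

Rendering accumulates each atom only over the voxel window intersecting
its kernel support, so gridding is O(atoms), not O(atoms × voxels). The
analytic gradient of the L2 objective with respect to atom coordinates
uses the same windows and is validated against central finite differences
at 1e−5 tolerance.

Pose augmentation draws rotations uniformly from SO(3) and translations
uniformly in ±2 Å per axis (the translation amplitude is a package
default chosen as a standard augmentation scale for 0.5 Å grids; it is
configurable).

## Atom fitting

Fitting inverts `G_ref` by alternating detection and refinement:

* **Detection**: strict 26-neighbor local maxima of the residual density
  on element channels, at or above `peak_threshold = 0.25`; ties break by
  value then lexicographic voxel index. Property channels never seed
  atoms — they only decorate an element peak (threshold 0.5) — which
  resolves the representational ambiguity of one atom being active in
  several channels at once.
* **Refinement**: plain gradient descent on all coordinates with
  backtracking step halving (start 0.1 Å-scale, 8 halvings max, gentle
  growth on success), best iterate kept, up to 100 steps with an early
  stop on stagnation.

Rounds add one atom by default (`atoms_per_round`, `beam_width`
configurable; a beam keeps the best `beam_width` structures by L2) and
are accepted while L2 improves by more than `convergence_tol = 1e−4`
relative; fitting also stops at `max_atoms = 80` or an empty candidate
list. The residual grid and the scalar loss are maintained incrementally
over each atom's support window, making a 20-atom fit on a 48³ grid take
about a second on one CPU.

On toy single-channel 8³ grids the greedy fit is checked against an
exhaustive oracle: every placement of 1–2 atoms on candidate lattice
sites is scored in closed form from per-candidate inner products, and the
top-ranked placements are refined with the same refiner. Ranking before
refining is safe because refinement only removes the sub-voxel mismatch,
which is far smaller than the cost of leaving a density blob unexplained.

## Bond inference

A deterministic rule sequence, normative for this package:

1. propose bonds for `0.4 Å < d ≤ r_i + r_j + 0.45 Å` (Cordero 2008
   covalent radii, embedded as data);
2. while an atom exceeds its maximum valence in bond count, drop its
   longest bond;
3. rings of size 5–6 whose atoms are all aromatic-typed become aromatic;
   a Kekulé structure is a maximum matching over ring atoms eligible for
   a double bond (carbons, and 2-coordinate non-donor N/P; O, S,
   donor-flagged and 3-coordinate nitrogens contribute a lone pair);
   an uncovered eligible atom marks the molecule invalid
   ("kekulization/aromaticity failure");
4. remaining orders rise from 1, shortest bonds first, when the length
   ratio to the radius sum is ≤ 0.93 (double) or ≤ 0.82 (triple) and both
   atoms have free valence;
5. formal charges come from the type vectors' charge block, never
   re-perceived from geometry — the type channels are the model's output
   contract;
6. implicit hydrogens fill the smallest admissible valence
   (charge-adjusted; e.g. N: 3+q, O: 2+q, C: 4−|q|, S: 2/4/6) that
   accommodates the bond-order sum; donor-typed atoms must end with ≥ 1 H
   or the molecule is invalid.

Validity additionally requires a single connected fragment and a
successful RDKit sanitization of the kekulized result. Stereochemistry,
protonation-state enumeration and tautomer canonicalization are out of
scope.

## CVAE

The model is written on a small numpy reverse-mode autodiff engine
(`gridmol.nn`): 3D convolution by im2col, average pooling,
nearest-neighbor upsampling, dense layers, leaky ReLU (slope 0.1),
softplus output, RMSprop. Architectural choices where the topology left
freedom:

* conv blocks are `leaky_relu(conv3x3x3)` with an identity residual when
  channel counts match;
* the decoder uses nearest-neighbor upsampling followed by convolution in
  place of transposed convolution (equivalent expressiveness, avoids
  checkerboard artifacts);
* skip features from the conditional encoder enter the decoder by channel
  concatenation at matching resolutions; the latent and conditional
  vectors are concatenated before the decoder's dense stem;
* the posterior σ comes from an `exp` of a log-std head, guaranteeing
  positivity;
* spectral normalization (one power iteration per forward pass, gradient
  flowing through the normalized weight, buffers frozen during inference
  so that repeated encodes are bit-identical) applies to all conv and
  dense weights and is toggleable.

Reference training settings: latent dimension 128, widths (32, 64, 128)
over 3 pooling levels on 48³ grids, RMSprop at 1e−5, batch 8, 10⁶
iterations, KL weight ramp 0.1 → 1.6 linear over 200k iterations from
iteration 450k. The reconstruction loss is the summed squared voxel
error (a Gaussian likelihood up to constants; a mean form is selectable).
The steric term of the training loss is numerically identical to the
`steric_overlap` grid functional applied to (receptor, generated ligand).

Full-corpus training is far beyond desk scale; trainability is instead
demonstrated by overfitting 5 synthetic complexes on 12³ grids with a
reduced model (latent 8, widths (6, 12), learning rate 1e−3, batch 5,
150 iterations, augmentation off), which cuts the reconstruction loss by
more than 90% — evidence that gradients, optimizer and architecture are
wired correctly, not a statement about generative quality.

## Sampling

`z' = μ + λ_var·σ·ε` with ε drawn i.i.d. standard normal (the printed
form of the equation overloads the symbol z; the right-hand draw is
reparameterization noise). The bias factor interpolates distribution
parameters linearly: `μ' = λ_bias·μ_post`, `σ' = λ_bias·σ_post +
(1−λ_bias)`, so 0 is exactly the prior and 1 exactly the posterior.
Spherical interpolation between latent endpoints of unequal norm rotates
the direction at constant angular speed and interpolates norms linearly;
antiparallel endpoints fall back to linear interpolation with a warning.
Grid centers along an interpolation trajectory interpolate the endpoint
ligands' centers linearly. Each sample index derives its own RNG stream
from the master seed, so sample k is reproducible regardless of how many
samples are requested.

## Evaluation metrics

Valid = single fragment + sanitizable; novel/unique = canonical SMILES
membership tests, computed over valid molecules (canonical SMILES is
undefined otherwise) with the over-all-samples percentages also reported.
The fingerprint defaults to the RDKit 2048-bit path fingerprint (Morgan
selectable); per-target diversity is the inverse mean pairwise Tanimoto
over unordered distinct pairs, undefined below two molecules. Two empty
fingerprints compare as 1 for identical canonical SMILES, else 0. UFF
relaxation minimizes the molecule's internal degrees of freedom (receptor
atoms, when provided, are added as fixed points) and reports the energy
change and the heavy-atom RMSD under the identity atom mapping — pre- and
post-poses share atom indices, so no symmetry correction is applied.

## Dataset rules

Docked-pose filtering keeps poses with RMSD to the crystal pose ≤ 2 Å
(the boundary is inclusive-keep, since only "greater than 2 Å" is
excluded) and drops ligands failing sanitization. Test-target selection
draws 10 distinct pocket clusters uniformly among targets with ≥ 5 unique
ligands, one target per cluster, rank-1 pose per ligand. The external
corpus itself is never downloaded: the rules are exercised on synthetic
pose records, and a loader path exists for users who have the data.

## Synthetic fixtures — what they show and what they do not

The fixture generator produces (a) random typed atoms with ≥ 2 Å pairwise
separation in a box, covering all 11 ligand elements across seeds, (b) an
aromatic hexagon with 1.39 Å sides, (c) carbon chains, (d) 3D conformers
(ETKDG + UFF) of a curated list of 32 small drug-like molecules, and
(e) cavity complexes: a Fibonacci-sphere receptor shell guaranteed to
keep ≥ 3.2 Å from every ligand atom, hence provably zero steric overlap
under the default kernel (a shrunken gap is the negative control). All
generation is deterministic per seed.

These fixtures establish correctness of the representation and the
inverse pipeline: well-separated atoms make density blobs unambiguous, so
near-perfect recovery rates are expected and achieved. Real molecules
have 1.2–1.5 Å bonded neighbors whose densities overlap; the curated-list
round trip covers that regime for small drug-like chemistry, but none of
the tests measure generative quality of a fully trained model on real
docked complexes — that requires the full corpus and training budget.

## Numerical choices

Grids are float64 throughout. The fitting loss is tracked incrementally;
its drift relative to a full recomputation is far below the 1e−2
acceptance scale. Peak ties break lexicographically; bond-order raising
processes shortest bonds first; all orderings are deterministic so
identical inputs give identical molecules. Degenerate inputs are defined:
empty grids fit to zero atoms with zero loss, empty structures render
zero grids, molecules with no atoms are invalid with reason "no atoms".

## Problem sizes used by the test suite and acceptance script

Density round trips run 200 (suite) / 100 (script) seeded fixtures of
5–20 atoms on default 48³ grids; the fitting oracle runs 50 / 20 toy 8³
grids; SMILES recovery covers the full 32-molecule curated list; the
trainability check runs 150 RMSprop iterations on five 12³ complexes.
These sizes keep a complete run in the minutes range on a single CPU
while leaving the statistics stable across seeds.
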