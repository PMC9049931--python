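# Methods

This note documents the models, conventions and numerical choices behind
`amphitraj`, and what the synthetic-data generators do and do not
emulate.

## Data model and units

Coordinates are Ångström everywhere internally (GRO nanometre values are
converted on read); masses are amu, electron counts are the neutral-atom
Z, times are picoseconds, temperatures Kelvin, entropies J K⁻¹ mol⁻¹ and
TΔS values kJ mol⁻¹. Atom and residue indices are 0-based internally and
1-based only at file boundaries. Only orthorhombic periodic boxes are
supported; triclinic input raises an explicit error. File reading and
writing for PDB/GRO/XYZ goes through MDAnalysis (with a header-CRYST1
fallback for multi-model PDB boxes, which MDAnalysis attaches only to
single-frame reads); the LAMMPS-style text dump has a dedicated reader
so that malformed frames fail with the offending timestep named.
`molecule_id` round-trips through the PDB chain identifier (up to 62
molecules); GRO carries no chain concept, so each GRO residue becomes
its own molecule.

## Aggregate detection

Two molecules are linked when any pair of qualifying atoms (heavy atoms
by default) lies within a cutoff under the minimum-image convention;
clusters are the connected components of that molecule graph
(single-linkage). The default cutoff is 4.5 Å, a common choice for
lipid-aggregation linkage; cutoff and atom set are explicit parameters
because different communities use different conventions. Neighbor
search uses a periodic k-d tree; the cutoff must stay below half the
smallest box length for the minimum image to be valid, and violating
this raises. Each molecule is first made whole relative to its first
atom, then cluster members are placed by breadth-first traversal of the
linkage graph, shifting each newly reached molecule by the lattice
vector that reconciles its linking atom pair — so a cluster straddling
the periodic boundary unwraps into one contiguous object regardless of
which image each coordinate was stored in.

## Shape metrics

The gyration tensor of a particle set about its center is
S_mn = Σ w_i (r^i_m − c_m)(r^i_n − c_n) / Σ w_i. The default weighting
is uniform (the tensor of "particle positions"); mass weighting is an
option. Its sorted eigenvalues (principal moments, Å²) give
Rg = √(λx²+λy²+λz²) — the square root is required for a length — and the
relative shape anisotropy κ² = (3/2)Σλ⁴/(Σλ²)² − 1/2, the standard
dimensionless eigenvalue combination that is 0 for any spherically
symmetric object (all moments equal), 1 for a line, and 1/4 for a thin
disc. Moments are scaled by their maximum before the κ² ratio is formed
so denormal traces cannot produce NaN; an all-zero tensor returns
κ² = 0 by convention. Shape time series unwrap the selection per frame
through the cluster machinery before evaluating the tensor.

Two centers appear in the aggregate analyses and are deliberately
distinct: the gyration tensor uses the same-weighting (by default
geometric) center of the cluster, while the per-residue distance
profile measures to the mass-weighted aggregate COM, matching the
"center of mass" language of that observable. Per-residue distances
subtract the unweighted mean over the peptide's residues, so each
peptide's relative distances sum to zero; replicate peptides are
averaged with a sample SD, and hydrophilic (charged + polar) versus
hydrophobic class means are reported.

## Pair distribution function

g(r) = ⟨n_ab(r, r+dr)⟩ / (4π r² dr ρ_b), averaged over frames and
a-atoms, with minimum-image distances and the partner density ρ_b taken
from each frame's instantaneous box volume. Counting uses cumulative
periodic-tree neighbor counts differenced over the bin edges; self
pairs (overlapping selections) sit exactly at d = 0 and are excluded by
the r = 0 edge. r_max must not exceed half the smallest box length.

## Scattering

The Debye sum is evaluated either directly over all pairs or via a
distance histogram (default bin 0.01 Å), which agrees with the direct
sum to well below 0.5% and is used automatically above 1500 atoms. The
default scattering length is the q-independent electron count Z_i; the
Cromer–Mann 4-Gaussian form factor (International Tables coefficients,
f(0) ≈ Z verified in the tests) is available per element, evaluated by
element-pair distance histograms. Hydrogens are included; no solvent
subtraction is applied (the sum is over the selected aggregate atoms in
vacuo), with a constant-background option left to downstream users.
A finite set of n point scatterers sampling a continuum body carries an
irreducible incoherent term Σb² ≈ I(0)/n, so agreement with a continuum
form factor is only meaningful where the coherent signal dominates that
floor; the sphere-oracle test therefore compares where the analytic
form factor exceeds 20/n.

Bilayer intensity uses the electron-density contrast profile along the
membrane normal: F(q) = Σ_j Δρ(z_j) e^{iqz_j} Δz on bin centers
(midpoint rule — spectrally accurate for smooth profiles, verified to
1e-6 against the Gaussian closed form) and I(q) = |F(q)|²/q², the
flat-sheet Lorentz factor. Density profiles deposit each atom's full
electron count at its center coordinate (no atomic spreading), divided
by the bin slab volume and averaged over frames.

`mix_curves` is plain pointwise linear combination (weights summing
to 1, linear resampling onto the first grid over the common overlap);
an optional flag first normalizes each curve to I = 1 at the smallest
shared q. `fit_mixture` always uses that normalization, because the
absolute scales of simulated and measured curves are unrelated: it
minimizes the RMSD of log₁₀ I between the scaled mixture and the target
for q above a cutoff (default 0.09 Å⁻¹, the regime where aggregate form
factors rather than inter-particle structure dominate), with the global
scale solved in closed form as a log offset. Two-component fits scan
the weight axis at 10⁻³ resolution and return the full RMSD-vs-weight
curve; more components use Nelder–Mead on a softmax parametrization
with multi-starts.

## Secondary structure

Hydrogen bonds use the Kabsch–Sander electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, with a bond
when E < −0.5 kcal/mol; |i−j| < 2 pairs are excluded and overlapping
atoms (< 0.1 Å) are treated as non-bonds. Missing amide hydrogens are
rebuilt geometrically (1.0 Å from N, opposite the bisector of the
C(i−1)–N and Cα–N directions); the first residue carries no donor.
Labels (priority H > G > E > T > C): a residue is α-helical (H) when it
is strictly enclosed by two consecutive i→i+4 hydrogen-bonded turns
*and* its (φ, ψ) lie in the helical window φ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°] — on an ideal 20-mer helix this labels residues 3–18,
trimming two residues per terminus, which is the STRIDE-like behaviour
of ending helices one residue earlier than a pure two-turn rule would.
3₁₀ (G) residues are the analogues enclosed by consecutive i→i+3 turns;
strand (E) comes from mutually hydrogen-bonded distant-residue bridges;
isolated 3- or 4-turns mark their interior as turn (T); everything else
is coil (C). Exact output parity with the STRIDE program is not
claimed — its fitted empirical energy surfaces are proprietary detail —
only the same physical inputs (hydrogen-bond energies and torsions).
Helicity counts H labels only (not G), as a per-frame residue fraction
with a population SD over frames; frames can be subsampled at a stride
that must divide into the frame spacing.

## Superposition, RMSD

Kabsch superposition via SVD with the determinant sign correction
(proper rotations only), optional weights, ≥3 non-collinear fit atoms
required. RMSD series superpose each frame onto a reference frame over
the selection and can exclude a trailing span of the selection (the
mobile C-terminal α-carbons of an amphipathic peptide being the typical
use). Values are stored in Å; the CLI also reports nm, the unit RMSD
plots in this field usually use.

## Conformational entropy

The covariance σ of Cartesian fluctuations about the time-mean
structure is accumulated after mass-weighted Kabsch alignment of every
frame onto a reference (align=True, the default for real trajectories).
The eigenvalues λ of M^{1/2} σ M^{1/2} give

- Schlitter: S = (R/2) Σ ln[1 + (k_B T e²/ħ²) λ] — e is Euler's number,
  not the elementary charge; the expression is an upper bound on the
  true entropy;
- quasi-harmonic: ω = √(k_B T/λ), x = ħω/k_B T,
  S = R Σ [x/(eˣ−1) − ln(1−e⁻ˣ)] — the quantum harmonic oscillator
  entropy at the effective frequencies.

Eigenvalues below 1e-8 of the largest are discarded as rigid-body
remnants of the superposition (they would otherwise contribute spurious
ln(1+ε) terms); stiff quasi-harmonic modes are clipped at x = 500 where
their contribution is already zero to machine precision. Constants are
CODATA via scipy. The block protocol splits the trajectory into
contiguous blocks (trailing frames dropped with a warning), computes
each block independently with per-block self-alignment, and reports the
sample mean ± SD; TΔS differences take two scalar entropies (block
means by default) and a temperature. The t-test is the pooled-variance
("standard Student") two-sided variant; two identical constant samples
return p = 1 by convention.

One covariance subtlety is a deliberate design choice: the
harmonic-ensemble generator draws iid Gaussian displacements about a
fixed laboratory-frame reference, with no rigid-body motion. Kabsch
alignment of such an ensemble absorbs ~6 degrees of freedom of genuine
fluctuation variance (for a 3-atom ensemble, 6 of its 9 modes), so the
validation of the estimators against the analytic Σ₀ entropies uses
align=False. Real trajectories tumble and drift, so alignment stays the
default there; rotating a fixture rigidly and re-analysing with
alignment reproduces the aligned entropy, which the tests check
separately.

The atom group entering the covariance is a mandatory, logged parameter
(all selected atoms by default; Cα-only or heavy-atom analyses are one
selection away), because absolute entropy values depend strongly on it.

## Synthetic generators

Every generator is seed-deterministic (identical seed + parameters give
bit-identical output) and emits a machine-readable ground-truth
dictionary, written as a JSON sidecar next to any exported fixture, so
tests never re-derive what the generator already knows.

- `gen_uniform_ball` / `gen_rod`: uniform samples of a ball or segment;
  analytic Rg = √(3/5)·R and L/√12, κ² → 0 and 1.
- `gen_harmonic_ensemble`: iid Gaussian fluctuations with a known
  diagonal covariance (Å²) about a fixed reference; analytic Schlitter
  and quasi-harmonic entropies emitted. 50 000 frames put both
  estimators within 1% of the analytic values.
- `gen_ideal_helix`: NeRF-built backbone (N, H, Cα, C, O) with standard
  bond lengths/angles, ω = 180°, carbonyl O anti to the next amide N,
  at any uniform (φ, ψ). At (−57°, −47°) the construction yields
  i→i+4 hydrogen-bond geometry (O···H ≈ 2.1 Å, E ≈ −2.2 kcal/mol);
  torsion read-back inverts the build to < 0.5°.
- `gen_toy_micelle_trajectory`: coarse amphiphiles (head bead + tail
  beads, tails inward with the innermost beads clustered at the core so
  all lipids are linkage-connected) plus surface-wrapped peptide bead
  chains anchored within linkage range of a head bead; odd frames
  translate the aggregate onto a box corner so its wrapped coordinates
  straddle the periodic boundary. Defaults are the 15-lipid/1-peptide
  and (with two aggregates) 14-lipid/2-peptide stoichiometries of small
  lipid/peptide micelles. Ground truth: molecule partition, per-frame
  unwrapped COMs, frame-0 Rg.
- `gen_slab_system`: bulk water (three-site molecules at a requested
  mass density, default 0.997 g/cm³ ⇒ 0.333 e/Å³) or a dense slab of
  stated thickness (default 31.9 Å, a typical monoolein membrane) in
  water. Frames are independent re-draws, emulating an equilibrated
  fluid's frame-to-frame decorrelation.

What the generators do *not* emulate: force-field energetics, realistic
chain packing and density correlations (g(r) of generated water is
structureless), peptide side chains, slow collective dynamics, or
finite-time correlation between frames. Passing tests therefore
demonstrate the correctness of the estimators and their convergence on
known ground truth — not that any specific simulated system's absolute
Rg, helicity or entropy is reproduced, which would require the original
trajectories.

## Problem sizes

The shipped tests and the acceptance script use desk-scale sizes chosen
to make the statistical tolerances meaningful: 10⁴-point shape oracles,
2000-point Debye spheres, 50 000-frame harmonic ensembles, ~900-water
slabs over 20 independent frames, 25-frame ideal-gas g(r) stacks. Each
completes in seconds on one CPU.

## Known limitations

- Only orthorhombic boxes; no triclinic minimum image.
- Cluster unwrapping assumes each molecule is smaller than half the
  box.
- The secondary-structure assignment approximates STRIDE's decision
  surface with published physical criteria; per-residue agreement with
  STRIDE on borderline geometries is not guaranteed.
- Electron-density profiles use point atoms (no form-factor spreading
  along z), adequate at the ≥0.5 Å bins used here.
- Mixture fitting assumes the components' relative normalization at the
  smallest shared q; if a measured target's low-q region is distorted
  (e.g. by structure factor or beam smearing), the recovered fractions
  inherit that convention.
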