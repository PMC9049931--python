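# amphitraj

Trajectory analysis for lipid/antimicrobial-peptide self-assembly.

`amphitraj` is a Python library for characterizing how surfactant-like
lipids (such as glycerol monooleate, GMO) and amphipathic peptides (such
as the human cathelicidin LL-37) co-assemble into micelles and bilayers
in molecular simulations. It bundles the analyses that such a study
needs — aggregate detection, shape metrics, small-angle X-ray scattering
from coordinates, per-residue positioning, secondary structure, RMSD and
conformational entropy — together with seed-deterministic synthetic
generators with analytically known properties, so every stage can be
validated without access to the original MD trajectories.

## What it computes

**Aggregate geometry.** Single-linkage molecular clusters under periodic
boundaries (minimum-image linkage, clusters unwrapped to be contiguous),
and the gyration tensor of a cluster about its center,

    S_mn = Σ_i w_i (r^i_m − c_m)(r^i_n − c_n) / Σ_i w_i ,

whose sorted eigenvalues λx² ≥ λy² ≥ λz² give the radius of gyration
Rg = √(λx²+λy²+λz²) and the relative shape anisotropy
κ² = (3/2)·(λx⁴+λy⁴+λz⁴)/(λx²+λy²+λz²)² − 1/2 (0 for a sphere, 1 for a
line). Also: per-residue center-of-mass distance profiles for bound
peptides (peptide-mean removed, with hydrophilic/hydrophobic class
means) and pair distribution functions g(r).

**Scattering.** Debye-equation SAXS from atomic coordinates,

    I(q) = Σ_i Σ_j b_i b_j sin(q r_ij)/(q r_ij),

with b_i the electron count (or optionally the Cromer–Mann q-dependent
form factor); electron-density profiles ρ(z); flat-sheet bilayer
intensity I(q) = |∫ Δρ(z) e^{iqz} dz|²/q²; and least-squares fitting of
linear mixtures of simulated curves to a target curve by the RMSD of
log₁₀ I above a q cutoff.

**Peptide conformation.** Backbone φ/ψ torsions, Kabsch–Sander
hydrogen-bond energies, STRIDE-style H/G/E/T/C secondary-structure
labels and helicity series, Kabsch superposition and RMSD series, and
residue-class composition of sequences (charged / polar / hydrophobic,
net charge at pH 7).

**Conformational entropy.** Mass-weighted covariance of aligned
fluctuations; Schlitter's upper-bound entropy
S = (R/2) ln det[1 + (k_B T e²/ħ²) M^{1/2} σ M^{1/2}] and the
quasi-harmonic oscillator entropy from the same eigenvalues; the
block-averaging protocol (contiguous, self-aligned blocks with mean ±
SD); TΔS differences in kJ/mol; pooled-variance Student t-tests.

## Worked example

```python
import amphitraj as at

traj, truth = at.gen_toy_micelle_trajectory(n_lipids=15, n_peptides=1,
                                            n_frames=4, box=60.0, seed=7)
clusters = at.find_clusters(traj, 0, cutoff=4.5)
df = at.shape_timeseries(traj)
print(len(clusters), df.attrs["mean"])

res = at.classify_residues(at.LL37_SEQUENCE)
print(res.percent, res.net_charge)

print(at.entropy_difference(9012.0, 7771.0, 310.0))
```

prints

```
1 {'Rg_A': 8.02803363610923, 'kappa2': 0.020255237585168423}
{'charged': 43, 'polar': 14, 'hydrophobic': 43} 6
384.71
```

— one aggregate containing all 16 molecules, a nearly spherical shape
(κ² ≈ 0.02 ≪ 1) of Rg ≈ 8 Å, the 43/43/14% charged/hydrophobic/polar
composition of LL-37 with its +6 net charge, and the TΔS ≈ 385 kJ/mol
entropy gap between a random-coil and an α-helical peptide state
computed from their block-averaged entropies at 310 K.

The `examples/` directory holds one short script per capability
(aggregate shape, SAXS mixture fitting, secondary structure, entropy,
density profiles); each prints the numbers it computes and a line on
what they mean.

## Command line

A thin CLI wraps the library:

```bash
amphitraj simulate --kind micelle --seed 7 --outdir sim
amphitraj shape --input sim/micelle.pdb --outdir shape_out
amphitraj classify
```

Subcommands: `clusters`, `shape`, `gofr`, `residues`, `saxs`,
`bilayer-saxs`, `fit-mix`, `ss`, `helicity`, `rmsd`, `entropy`,
`classify`, `simulate`. Every run echoes its effective YAML config and a
log into the output directory; unknown config keys are rejected, and
reruns with the same inputs are byte-identical.

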