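"""Debye SAXS of a micelle, bilayer scattering, and a 21/79 mixture fit.

Computes I(q) of a toy micelle via the Debye equation, I(q) of a bilayer
slab from its electron-density contrast profile, combines them 21%
bilayer / 79% micelle, and then recovers that split by least-squares
mixture fitting on log-intensity above q = 0.09 1/A — the workflow used
to reconcile simulated aggregate scattering with a measured curve that
contains both micelles and vesicles.
"""

import numpy as np

import amphitraj as at

q = np.linspace(0.02, 0.5, 120)

mic, _ = at.gen_toy_micelle_trajectory(n_lipids=15, n_peptides=1,
                                       n_frames=1, seed=7)
cluster = at.find_clusters(mic, 0)[0]
micelle_curve = at.debye_intensity(
    None, None, q_grid=q, positions=cluster.unwrapped_positions,
    b=mic.electron_counts[cluster.atom_indices])
print(f"micelle I(q): I(q_min)/I(q_max) = "
      f"{micelle_curve.intensity[0] / micelle_curve.intensity[-1]:.1f}")

slab, _ = at.gen_slab_system("bilayer", box=(25, 25, 70), n_frames=20, seed=8)
profile = at.electron_density_profile(slab, "z", bin_width=1.0)
bilayer_curve = at.bilayer_intensity(profile, solvent_density=0.333, q_grid=q)

target = at.mix_curves([bilayer_curve, micelle_curve], [0.21, 0.79],
                       normalize=True)
fit = at.fit_mixture([bilayer_curve, micelle_curve], target, q_min=0.09)
print(f"recovered mixture: {100 * fit.weights[0]:.0f}% bilayer / "
      f"{100 * fit.weights[1]:.0f}% micelle "
      f"(rmsd of log10 I = {fit.rmsd:.2e})")
# A two-population mixture reproduces the 21/79 split exactly on this
# noiseless target; on measured data the same fit gives the best-RMSD
# bilayer (vesicle) fraction.
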