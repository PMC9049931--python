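"""Aggregate detection and shape metrics on a toy lipid/peptide micelle.

Builds a coarse 15-lipid + 1-peptide micelle (the stoichiometry of a
small amphiphile/peptide aggregate), detects it as a single-linkage
cluster under periodic boundaries — including frames where it straddles
the box edge — and reports the radius of gyration and relative shape
anisotropy per frame.
"""

import amphitraj as at

traj, truth = at.gen_toy_micelle_trajectory(
    n_lipids=15, n_peptides=1, n_frames=4, box=60.0, seed=7)

clusters = at.find_clusters(traj, 0, cutoff=4.5)
print(f"frame 0: {len(clusters)} cluster(s); "
      f"molecules {sorted(clusters[0].molecule_ids)}")
print(f"planted partition recovered: "
      f"{sorted(clusters[0].molecule_ids) == truth['partition'][0]}")

df = at.shape_timeseries(traj)
print(df[["time_ps", "Rg_A", "kappa2"]].to_string(index=False,
                                                  float_format="%.4f"))
m, s = df.attrs["mean"], df.attrs["sd"]
print(f"Rg = {m['Rg_A']:.2f} +/- {s['Rg_A']:.2f} A, "
      f"kappa2 = {m['kappa2']:.3f} +/- {s['kappa2']:.3f}")
# kappa2 near zero means the aggregate is nearly spherical; Rg tracks
# its overall size. Values are stable across the boundary-straddling
# frames because clusters are unwrapped before the tensor is evaluated.
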