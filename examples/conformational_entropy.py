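"""Schlitter and quasi-harmonic entropy with block averaging.

Samples a harmonic fluctuation ensemble with a known covariance, checks
both estimators against the analytic values, runs the block-averaging
protocol, and converts an entropy difference into T dS at 310 K — the
quantity that measures how much conformational freedom a peptide loses
when it binds a lipid aggregate.
"""

import numpy as np

import amphitraj as at
from amphitraj.entropy import aligned_covariance, quasiharmonic_entropy, \
    schlitter_entropy, two_sample_t_test

traj, truth = at.gen_harmonic_ensemble(
    masses=np.full(3, 12.011), sigma_diag=np.full(9, 0.04),
    temperature=310.0, n_frames=50_000, seed=13)

model = aligned_covariance(traj, align=False)
s_s = schlitter_entropy(model, 310.0)
s_q = quasiharmonic_entropy(model, 310.0)
print(f"Schlitter      : {s_s.entropy:8.2f} J/(K mol)  "
      f"(analytic {truth['S_schlitter_analytic']:.2f})")
print(f"quasi-harmonic : {s_q.entropy:8.2f} J/(K mol)  "
      f"(analytic {truth['S_quasiharmonic_analytic']:.2f})")
print(f"upper bound holds: {s_s.entropy >= s_q.entropy}")

blocks = at.block_entropy(traj, temperature=310.0, n_blocks=20, align=False)
print(f"block protocol : {blocks.entropy:.2f} +/- {blocks.sd:.2f} J/(K mol) "
      f"over {len(blocks.block_values)} blocks")

# T dS between two states from their published-style block averages
tds = at.entropy_difference(9012.0, 7771.0, 310.0)
print(f"T dS (9012 -> 7771 J/(K mol) at 310 K) = {tds:.1f} kJ/mol")

# block-level significance: compare two halves of the block values
half = len(blocks.block_values) // 2
t = two_sample_t_test(blocks.block_values[:half], blocks.block_values[half:])
print(f"stationarity t-test: t = {t['t']:.2f}, p = {t['p']:.2f}")
# Both estimators sit within a percent of the analytic entropy at this
# frame count, the Schlitter value bounds the quasi-harmonic one from
# above, and stationary blocks show no significant drift.
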