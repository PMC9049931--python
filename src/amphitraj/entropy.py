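"""Schlitter and quasi-harmonic conformational entropy.

Both estimators work from the mass-weighted covariance of Cartesian
fluctuations.  With sigma the 3n x 3n covariance (A^2) and M the
diagonal mass matrix, the eigenvalues lambda_k of M^{1/2} sigma M^{1/2}
(amu A^2) give

    Schlitter:       S = (R/2) sum_k ln[1 + (k_B T e^2 / hbar^2) lambda_k]
    quasi-harmonic:  omega_k = sqrt(k_B T / lambda_k),
                     x_k = hbar omega_k / k_B T,
                     S = R sum_k [ x_k/(e^{x_k} - 1) - ln(1 - e^{-x_k}) ]

in J K^-1 mol^-1.  ``e`` in Schlitter's formula is Euler's number, not
the elementary charge.  Schlitter's expression is an upper bound, so
S_schlitter >= S_quasiharmonic on any covariance.  Near-zero eigenvalues
(rigid-body remnants of the superposition) are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants, stats

from .conformation import superpose
from .core import Trajectory

__all__ = [
    "CovarianceModel", "EntropyResult", "aligned_covariance",
    "schlitter_entropy", "quasiharmonic_entropy", "block_entropy",
    "entropy_difference", "two_sample_t_test",
]

R_GAS = constants.R                 # J / (K mol)
_KB = constants.k                   # J / K
_HBAR = constants.hbar              # J s
_AMU = constants.atomic_mass        # kg
_A2 = 1e-20                         # m^2 per A^2

#: eigenvalues below this fraction of the largest are rigid-body remnants
RIGID_MODE_RELATIVE_THRESHOLD = 1e-8


@dataclass
class CovarianceModel:
    """Mass-annotated covariance of aligned Cartesian fluctuations."""

    selection: np.ndarray          # atom indices
    reference: np.ndarray          # alignment target coordinates, A
    sigma: np.ndarray              # 3n x 3n covariance, A^2
    masses: np.ndarray             # amu per coordinate (each atom x3)
    n_frames: int

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        dim = 3 * len(self.selection)
        if self.sigma.shape != (dim, dim):
            raise ValueError(f"covariance must be {dim}x{dim}")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    def mass_weighted_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of M^{1/2} sigma M^{1/2} in amu A^2, descending."""
        sqm = np.sqrt(self.masses)
        mw = self.sigma * sqm[:, None] * sqm[None, :]
        vals = np.linalg.eigvalsh(mw)[::-1]
        if vals[-1] < -1e-6 * max(vals[0], 1.0):
            raise ValueError("covariance is not positive semi-definite")
        return np.clip(vals, 0.0, None)


@dataclass
class EntropyResult:
    method: str                    # 'schlitter' or 'quasiharmonic'
    entropy: float                 # J / (K mol); block mean when blocked
    temperature: float             # K
    block_values: list[float]
    sd: float                      # sample SD over blocks (0 for one block)

    @property
    def mean(self) -> float:
        return self.entropy


def aligned_covariance(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    reference_frame: int = 0,
    align: bool = True,
) -> CovarianceModel:
    """Covariance of Cartesian fluctuations about the time-mean structure.

    With ``align=True`` (default) every frame is first superposed onto
    the reference frame with a mass-weighted Kabsch fit, removing
    rigid-body motion.  ``align=False`` is appropriate for ensembles
    generated in a fixed laboratory frame (e.g. the harmonic-ensemble
    oracle), where superposition would absorb genuine fluctuations.
    """
    if selection is None:
        selection = np.arange(trajectory.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("selection must be non-empty")
    if trajectory.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    if trajectory.n_frames < 3 * len(selection) / 10:
        warnings.warn(
            f"only {trajectory.n_frames} frames for {3 * len(selection)} "
            "coordinates; covariance will be poorly conditioned", stacklevel=2)

    masses = trajectory.masses[selection]
    ref = trajectory.frames[reference_frame].positions[selection]
    coords = np.empty((trajectory.n_frames, len(selection), 3))
    for k, fr in enumerate(trajectory.frames):
        x = fr.positions[selection]
        if align:
            Rm, t, _ = superpose(x, ref, weights=masses)
            x = (Rm @ x.T).T + t
        coords[k] = x
    flat = coords.reshape(trajectory.n_frames, -1)
    delta = flat - flat.mean(axis=0)
    sigma = delta.T @ delta / trajectory.n_frames
    return CovarianceModel(
        selection=selection, reference=ref, sigma=sigma,
        masses=np.repeat(masses, 3), n_frames=trajectory.n_frames)


def _usable_modes(model: CovarianceModel) -> np.ndarray:
    vals = model.mass_weighted_eigenvalues()
    if vals[0] == 0.0:
        return np.array([])
    return vals[vals > RIGID_MODE_RELATIVE_THRESHOLD * vals[0]]


def schlitter_entropy(model: CovarianceModel, temperature: float) -> EntropyResult:
    """Schlitter upper-bound entropy of a covariance model, J K^-1 mol^-1."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    lam = _usable_modes(model)
    alpha = _KB * temperature * np.e ** 2 / _HBAR ** 2 * _AMU * _A2
    s = 0.5 * R_GAS * float(np.sum(np.log1p(alpha * lam)))
    return EntropyResult("schlitter", s, temperature, [s], 0.0)


def quasiharmonic_entropy(model: CovarianceModel, temperature: float) -> EntropyResult:
    """Quasi-harmonic (quantum oscillator) entropy, J K^-1 mol^-1."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    lam = _usable_modes(model)
    if len(lam) == 0:
        return EntropyResult("quasiharmonic", 0.0, temperature, [0.0], 0.0)
    lam_si = lam * _AMU * _A2                       # kg m^2
    omega = np.sqrt(_KB * temperature / lam_si)     # rad/s
    x = _HBAR * omega / (_KB * temperature)
    # stiff modes (large x) contribute nothing; clip to avoid overflow
    x = np.minimum(x, 500.0)
    terms = x / np.expm1(x) - np.log1p(-np.exp(-x))
    s = R_GAS * float(np.sum(terms))
    return EntropyResult("quasiharmonic", s, temperature, [s], 0.0)


_METHODS = {"schlitter": schlitter_entropy, "quasiharmonic": quasiharmonic_entropy}


def analytic_entropy(sigma_diag: np.ndarray, masses_per_coord: np.ndarray,
                     temperature: float, method: str = "schlitter") -> float:
    """Entropy of a known diagonal covariance (generator ground truth)."""
    model = CovarianceModel(
        selection=np.arange(len(sigma_diag) // 3),
        reference=np.zeros((len(sigma_diag) // 3, 3)),
        sigma=np.diag(np.asarray(sigma_diag, dtype=float)),
        masses=np.asarray(masses_per_coord, dtype=float),
        n_frames=0)
    return _METHODS[method](model, temperature).entropy


def block_entropy(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    temperature: float = 310.0,
    n_blocks: int = 20,
    method: str = "schlitter",
    align: bool = True,
) -> EntropyResult:
    """Block-averaged entropy: contiguous blocks, each self-aligned.

    The trajectory is split into ``n_blocks`` contiguous sections
    (trailing frames dropped with a warning when not divisible); the
    entropy of each block is computed independently and the sample mean
    and SD over blocks reported.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    n = trajectory.n_frames
    if n_blocks < 1 or n_blocks > n:
        raise ValueError(f"n_blocks must be in 1..{n}")
    size = n // n_blocks
    if n % n_blocks:
        warnings.warn(f"dropping {n % n_blocks} trailing frames "
                      f"({n} not divisible by {n_blocks})", stacklevel=2)
    values = []
    for b in range(n_blocks):
        sub = Trajectory(topology=trajectory.topology,
                         frames=trajectory.frames[b * size:(b + 1) * size])
        model = aligned_covariance(sub, selection, reference_frame=0, align=align)
        values.append(_METHODS[method](model, temperature).entropy)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return EntropyResult(method, mean, temperature, values, sd)


def entropy_difference(s_a: float, s_b: float, temperature: float) -> float:
    """T (S_a - S_b) in kJ/mol; positive when state a has higher entropy."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return temperature * (s_a - s_b) / 1000.0


def two_sample_t_test(samples_a, samples_b) -> dict:
    """Two-sided pooled-variance Student t-test: {'t', 'df', 'p'}."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return {"t": 0.0, "df": df, "p": 1.0}
        return {"t": np.inf if a.mean() > b.mean() else -np.inf, "df": df, "p": 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": df, "p": float(p)}
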