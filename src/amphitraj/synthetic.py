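"""Seed-deterministic synthetic fixtures with analytically known properties.

Each generator returns a :class:`~amphitraj.core.Trajectory` plus a
ground-truth dictionary (and embeds a :class:`GeneratorSpec`), so every
analysis stage can be validated without molecular-dynamics runs:
uniform balls and rods for the gyration/anisotropy limits and the sphere
form factor, Gaussian harmonic ensembles with a known covariance for the
entropy estimators, ideal polypeptide backbones for torsion and
secondary-structure checks, toy micelles with planted cluster partitions
for aggregate detection, and water/bilayer slabs for electron-density
profiles.  Geometry is deliberately coarse (beads, not chemistry): the
analysis operators need only positions, masses and electron counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .conformation import dihedral
from .core import Atom, Box, Frame, Trajectory
from .elements import element_mass, element_number
from .entropy import analytic_entropy

__all__ = [
    "GeneratorSpec", "gen_uniform_ball", "gen_rod", "gen_harmonic_ensemble",
    "gen_ideal_helix", "gen_toy_micelle_trajectory", "gen_slab_system",
    "write_fixture",
]


@dataclass(frozen=True)
class GeneratorSpec:
    kind: str
    parameters: dict
    seed: int | None


def _atoms_of(element: str, n: int, **kwargs) -> list[Atom]:
    return [Atom.from_element(i, element, **kwargs) for i in range(n)]


def _result(traj: Trajectory, truth: dict, spec: GeneratorSpec):
    truth = dict(truth)
    truth["generator"] = asdict(spec)
    return traj, truth


# ---------------------------------------------------------------------------


def gen_uniform_ball(n: int, radius: float, seed: int = 0):
    """n points uniform in a ball of the given radius (A), centered at 0.

    Ground truth: Rg_analytic = sqrt(3/5) R (second moment of a uniform
    ball), kappa2 -> 0 by spherical symmetry.
    """
    if n < 1 or radius <= 0:
        raise ValueError("need n >= 1 and radius > 0")
    rng = np.random.default_rng(seed)
    if n == 1:
        pos = np.zeros((1, 3))
    else:
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius * rng.random(n) ** (1.0 / 3.0)
        pos = v * r[:, None]
    traj = Trajectory(topology=_atoms_of("C", n),
                      frames=[Frame(pos, Box.nonperiodic())])
    truth = {"rg_analytic_A": float(np.sqrt(3.0 / 5.0) * radius) if n > 1 else 0.0,
             "kappa2_analytic": 0.0, "radius_A": radius}
    return _result(traj, truth, GeneratorSpec("uniform_ball",
                   {"n": n, "radius": radius}, seed))


def gen_rod(n: int, length: float, seed: int = 0):
    """n points uniform on a randomly oriented segment of given length (A).

    Ground truth: kappa2 -> 1 (line limit), Rg -> L/sqrt(12).  n = 2
    places the two endpoints exactly.
    """
    if n < 2 or length <= 0:
        raise ValueError("need n >= 2 and length > 0")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    if n == 2:
        s = np.array([-0.5, 0.5]) * length
    else:
        s = (rng.random(n) - 0.5) * length
    pos = s[:, None] * u[None, :]
    traj = Trajectory(topology=_atoms_of("C", n),
                      frames=[Frame(pos, Box.nonperiodic())])
    truth = {"kappa2_analytic": 1.0,
             "rg_analytic_A": float(length / np.sqrt(12.0)),
             "length_A": length}
    return _result(traj, truth, GeneratorSpec("rod", {"n": n, "length": length}, seed))


def gen_harmonic_ensemble(
    masses: np.ndarray,
    sigma_diag: np.ndarray,
    temperature: float = 310.0,
    n_frames: int = 5000,
    seed: int = 0,
):
    """iid Gaussian fluctuation ensemble with known diagonal covariance.

    Atoms sit on a line (3 A spacing); each frame adds independent
    zero-mean Gaussian displacements with the requested per-coordinate
    variances (A^2) in a fixed laboratory frame — there is no rigid-body
    motion, so covariance analysis of this ensemble should use
    ``align=False``.  Ground truth: Sigma_0 and the analytic Schlitter
    and quasi-harmonic entropies.
    """
    masses = np.asarray(masses, dtype=float)
    sigma_diag = np.asarray(sigma_diag, dtype=float)
    n_atoms = len(masses)
    if sigma_diag.shape != (3 * n_atoms,):
        raise ValueError("sigma_diag must have 3 entries per atom")
    if np.any(sigma_diag <= 0) or n_frames < 2:
        raise ValueError("sigma_diag must be positive and n_frames >= 2")
    rng = np.random.default_rng(seed)
    ref = np.zeros((n_atoms, 3))
    ref[:, 0] = 3.0 * np.arange(n_atoms)
    disp = rng.normal(size=(n_frames, 3 * n_atoms)) * np.sqrt(sigma_diag)
    frames = [Frame(ref + disp[k].reshape(n_atoms, 3), Box.nonperiodic(), time=float(k))
              for k in range(n_frames)]
    topology = [Atom(index=i, name=f"X{i}", element="C", mass=float(masses[i]),
                     electron_count=6, residue_index=i) for i in range(n_atoms)]
    traj = Trajectory(topology=topology, frames=frames)
    m3 = np.repeat(masses, 3)
    truth = {
        "sigma_diag_A2": sigma_diag.tolist(),
        "S_schlitter_analytic": analytic_entropy(sigma_diag, m3, temperature,
                                                 "schlitter"),
        "S_quasiharmonic_analytic": analytic_entropy(sigma_diag, m3, temperature,
                                                     "quasiharmonic"),
        "temperature_K": temperature,
    }
    return _result(traj, truth, GeneratorSpec(
        "harmonic_ensemble",
        {"n_atoms": n_atoms, "temperature": temperature, "n_frames": n_frames}, seed))


# ---------------------------------------------------------------------------
# ideal backbone builder

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# standard backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.0
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position of d given a-b-c, |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        -np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_ideal_helix(sequence: str, phi: float = -57.0, psi: float = -47.0):
    """Ideal polypeptide backbone (N, H, CA, C, O) at uniform (phi, psi).

    Standard bond lengths/angles, omega = 180 deg.  At the alpha-helical
    torsions (-57, -47) the construction produces i -> i+4 backbone
    hydrogen-bond geometry; at (180, 180) it is fully extended.  Ground
    truth: requested torsions and, for helical torsions, the residue
    span expected to be labeled H.
    """
    seq = sequence.strip().upper()
    if len(seq) < 4:
        raise ValueError("sequence must have at least 4 residues")
    n_res = len(seq)

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)

    O = np.zeros((n_res, 3))
    H = np.full((n_res, 3), np.nan)
    for i in range(n_res):
        # carbonyl O anti to the next amide N (torsion psi + 180)
        O[i] = _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        if i > 0:
            u1 = N[i] - C[i - 1]
            u2 = N[i] - CA[i]
            u = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            H[i] = N[i] + _B_N_H * u / np.linalg.norm(u)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    idx = 0
    for i, letter in enumerate(seq):
        resname = _ONE_TO_THREE[letter]
        entries = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i]),
                   ("O", "O", O[i])]
        if i > 0:
            entries.insert(1, ("H", "H", H[i]))
        for name, element, xyz in entries:
            atoms.append(Atom(index=idx, name=name, element=element,
                              mass=element_mass(element),
                              electron_count=element_number(element),
                              residue_index=i, residue_name=resname,
                              molecule_id=0))
            coords.append(xyz)
            idx += 1
    traj = Trajectory(topology=atoms,
                      frames=[Frame(np.stack(coords), Box.nonperiodic())])
    helical = (-100.0 <= phi <= -30.0) and (-80.0 <= psi <= -5.0)
    truth = {
        "phi_deg": phi, "psi_deg": psi, "sequence": seq,
        # H labels expected for residues strictly enclosed by two
        # consecutive i->i+4 turns (0-based, inclusive)
        "expected_h_span": [2, n_res - 3] if helical and n_res >= 6 else None,
    }
    return _result(traj, truth, GeneratorSpec(
        "ideal_helix", {"sequence": seq, "phi": phi, "psi": psi}, None))


# ---------------------------------------------------------------------------
# toy micelle


def _sphere_points(n: int, radius: float) -> np.ndarray:
    """~uniform points on a sphere (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi_ang = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return radius * np.column_stack([
        np.cos(theta) * np.sin(phi_ang),
        np.sin(theta) * np.sin(phi_ang),
        np.cos(phi_ang),
    ])


def gen_toy_micelle_trajectory(
    n_lipids: int = 15,
    n_peptides: int = 1,
    n_frames: int = 4,
    box: float = 60.0,
    seed: int = 0,
    n_aggregates: int = 1,
    peptide_sequence: str = "LLGDFFRKSK",
    jitter: float = 0.15,
    straddle_boundary: bool = True,
):
    """Coarse micelle trajectory with a planted cluster partition.

    Each aggregate: ``n_lipids`` head-plus-tail bead amphiphiles
    arranged radially (tails inward, innermost beads clustered near the
    center so all lipids are single-linkage connected), plus
    ``n_peptides`` bead chains wrapped on the surface, the first peptide
    bead anchored within linkage range of a head bead.  Odd frames
    (``straddle_boundary``) translate the first aggregate onto a box
    corner so its wrapped coordinates straddle the periodic boundary.
    Ground truth: the molecule partition, per-frame unwrapped aggregate
    COMs, and the frame-0 (uniform-weight) Rg of each aggregate.
    """
    if n_aggregates < 1 or n_lipids < 3:
        raise ValueError("need n_aggregates >= 1 and n_lipids >= 3")
    rng = np.random.default_rng(seed)
    r_head, tail_radii, r_core = 11.0, (8.0, 5.5), 1.5
    r_pep = 11.5

    aggregates: list[dict] = []
    atoms: list[Atom] = []
    base_pos: list[np.ndarray] = []
    mol_id = 0
    res_counter = 0
    idx = 0
    centers = [np.full(3, box / 2.0) + np.array([dx, 0.0, 0.0])
               for dx in np.arange(n_aggregates) * max(30.0, 3 * r_pep)]

    for agg, center in enumerate(centers):
        members = []
        heads = _sphere_points(n_lipids, r_head)
        cores = _sphere_points(n_lipids, r_core)
        for li in range(n_lipids):
            u = heads[li] / np.linalg.norm(heads[li])
            beads = [("O", heads[li])] + \
                    [("C", r * u) for r in tail_radii] + [("C", cores[li])]
            for name, xyz in beads:
                atoms.append(Atom(index=idx, name=name, element=name,
                                  mass=element_mass(name),
                                  electron_count=element_number(name),
                                  residue_index=res_counter, residue_name="GMO",
                                  molecule_id=mol_id))
                base_pos.append(center + xyz)
                idx += 1
            members.append(mol_id)
            mol_id += 1
            res_counter += 1
        for _ in range(n_peptides):
            # bead chain along a great circle at r_pep, starting 3 A from
            # a head bead so the peptide is linkage-connected
            anchor_head = heads[rng.integers(n_lipids)]
            axis = anchor_head / np.linalg.norm(anchor_head)
            ortho = np.cross(axis, rng.normal(size=3))
            ortho /= np.linalg.norm(ortho)
            start = (r_pep / r_head) * anchor_head
            arc = 3.8 / r_pep  # ~Calpha spacing on the sphere
            for ri, letter in enumerate(peptide_sequence):
                ang = ri * arc
                xyz = (np.cos(ang) * start + np.sin(ang) * r_pep *
                       np.cross(ortho, start / np.linalg.norm(start)))
                atoms.append(Atom(index=idx, name="CA", element="C",
                                  mass=element_mass("C"),
                                  electron_count=element_number("C"),
                                  residue_index=res_counter + ri,
                                  residue_name=_ONE_TO_THREE[letter],
                                  molecule_id=mol_id))
                base_pos.append(center + xyz)
                idx += 1
            members.append(mol_id)
            mol_id += 1
            res_counter += len(peptide_sequence)
        aggregates.append({"molecule_ids": members, "center0": center})

    base = np.stack(base_pos)
    the_box = Box((box, box, box))
    mol_of = np.array([a.molecule_id for a in atoms])
    agg_of_atom = np.empty(len(atoms), dtype=int)
    for gi, agg in enumerate(aggregates):
        agg_of_atom[np.isin(mol_of, agg["molecule_ids"])] = gi

    frames = []
    truth_coms = []
    rg0 = []
    for k in range(n_frames):
        pos = base + rng.normal(scale=jitter, size=base.shape)
        if straddle_boundary and (k % 2 == 1):
            pos = pos.copy()
            shift = -centers[0]  # put aggregate 0 on the box origin/corner
            pos[agg_of_atom == 0] += shift
        coms = []
        for gi in range(n_aggregates):
            p = pos[agg_of_atom == gi]
            coms.append(p.mean(axis=0).tolist())
            if k == 0:
                d = p - p.mean(axis=0)
                rg0.append(float(np.sqrt((d ** 2).sum(axis=1).mean())))
        truth_coms.append(coms)
        frames.append(Frame(the_box.wrap(pos), the_box, time=float(k)))

    traj = Trajectory(topology=atoms, frames=frames)
    truth = {
        "partition": [sorted(a["molecule_ids"]) for a in aggregates],
        "com_unwrapped_per_frame": truth_coms,
        "rg_frame0_A": rg0,
        "n_molecules": mol_id,
    }
    return _result(traj, truth, GeneratorSpec(
        "toy_micelle",
        {"n_lipids": n_lipids, "n_peptides": n_peptides, "n_frames": n_frames,
         "box": box, "n_aggregates": n_aggregates}, seed))


# ---------------------------------------------------------------------------
# slabs


_WATER_MOLAR_MASS = 18.015  # g/mol
_AVOGADRO = 6.02214076e23


def gen_slab_system(
    kind: str = "water",
    box: tuple[float, float, float] = (25.0, 25.0, 25.0),
    mass_density: float = 0.997,      # g/cm^3, water kind
    slab_thickness: float = 31.9,     # A, bilayer kind
    slab_electron_density: float = 0.45,  # e/A^3, bilayer kind
    n_frames: int = 1,
    seed: int = 0,
):
    """Water box or bilayer/water slab with known density profile.

    ``water``: three-site water molecules placed uniformly at the
    requested mass density; the analytic electron-density plateau is
    rho_e = 10 e * (rho_mass N_A / M_water).  ``bilayer``: a dense
    carbon slab of the stated thickness centered at Lz/2, water
    elsewhere.  Ground truth: plateau density and slab span.
    """
    rng = np.random.default_rng(seed)
    lx, ly, lz = box
    the_box = Box((lx, ly, lz))
    volume = lx * ly * lz
    rho_n = mass_density / _WATER_MOLAR_MASS * _AVOGADRO * 1e-24  # waters/A^3

    def water_atoms(n_mol, region_lo, region_hi, idx0, mol0):
        atoms, pos = [], []
        centers = rng.random((n_mol, 3)) * np.array([lx, ly, region_hi - region_lo])
        centers[:, 2] += region_lo
        for w in range(n_mol):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            perp = np.cross(axis, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            o = centers[w]
            h1 = o + 0.9572 * axis
            ang = np.radians(104.52)
            h2 = o + 0.9572 * (np.cos(ang) * axis + np.sin(ang) * perp)
            for name, xyz in (("OW", o), ("HW1", h1), ("HW2", h2)):
                el = name[0]
                atoms.append(Atom(index=idx0 + len(atoms), name=name, element=el,
                                  mass=element_mass(el),
                                  electron_count=element_number(el),
                                  residue_index=mol0 + w, residue_name="SOL",
                                  molecule_id=mol0 + w))
                pos.append(xyz)
        return atoms, pos

    def build_configuration():
        """One independent fluid configuration (frames are uncorrelated)."""
        atoms: list[Atom] = []
        positions: list[np.ndarray] = []
        if kind == "water":
            n_w = int(round(rho_n * volume))
            a, p = water_atoms(n_w, 0.0, lz, 0, 0)
            atoms += a
            positions += p
            truth = {"plateau_e_A3": 10.0 * n_w / volume,
                     "n_waters": n_w, "mass_density_g_cm3": mass_density}
        elif kind == "bilayer":
            z_lo = lz / 2.0 - slab_thickness / 2.0
            z_hi = lz / 2.0 + slab_thickness / 2.0
            n_c = int(round(slab_electron_density / 6.0 * lx * ly * slab_thickness))
            cpos = rng.random((n_c, 3)) * np.array([lx, ly, slab_thickness])
            cpos[:, 2] += z_lo
            for i in range(n_c):
                atoms.append(Atom(index=i, name="C", element="C",
                                  mass=element_mass("C"),
                                  electron_count=element_number("C"),
                                  residue_index=0, residue_name="MEM",
                                  molecule_id=0))
                positions.append(cpos[i])
            water_vol = lx * ly * (lz - slab_thickness)
            n_w = int(round(rho_n * water_vol))
            n_lower = int(round(n_w * z_lo / (lz - slab_thickness)))
            a, p = water_atoms(n_lower, 0.0, z_lo, len(atoms), 1)
            atoms += a
            positions += p
            a, p = water_atoms(n_w - n_lower, z_hi, lz, len(atoms), 1 + n_lower)
            atoms += a
            positions += p
            truth = {"slab_thickness_A": slab_thickness,
                     "slab_span_A": [z_lo, z_hi],
                     "slab_electron_density_e_A3": slab_electron_density,
                     "water_plateau_e_A3": 10.0 * rho_n}
        else:
            raise ValueError("kind must be 'water' or 'bilayer'")
        base = np.stack(positions) if positions else np.zeros((0, 3))
        return atoms, base, truth

    frames = []
    atoms = None
    truth = {}
    for k in range(n_frames):
        frame_atoms, base, truth = build_configuration()
        if atoms is None:
            atoms = frame_atoms
        frames.append(Frame(the_box.wrap(base), the_box, time=float(k)))
    traj = Trajectory(topology=atoms, frames=frames)
    return _result(traj, truth, GeneratorSpec(
        "slab", {"kind": kind, "box": list(box), "mass_density": mass_density,
                 "slab_thickness": slab_thickness, "n_frames": n_frames}, seed))


# ---------------------------------------------------------------------------


def write_fixture(trajectory: Trajectory, truth: dict, path, format="PDB") -> None:
    """Write a fixture through the standard writers plus a JSON sidecar.

    The sidecar (``<path>.json``) carries the ground truth and the
    generator spec; tests must never re-derive what the generator knows.
    """
    from .core import write_structure

    write_structure(trajectory, path, format=format)
    with open(f"{path}.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
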