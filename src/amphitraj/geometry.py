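"""Aggregate detection and geometric observables.

Implements the micelle-side analyses: single-linkage cluster detection
under periodic boundaries (with unwrapping so each cluster is
contiguous), the gyration tensor and its derived shape metrics (radius
of gyration and relative shape anisotropy), per-residue center-of-mass
distance profiles for bound peptides, and pair distribution functions.

The gyration tensor of a particle set about its center c is

    S_mn = sum_i w_i (r^i_m - c_m)(r^i_n - c_n) / sum_i w_i ,

whose eigenvalues are the principal moments lx^2 >= ly^2 >= lz^2.  The
radius of gyration is Rg = sqrt(lx^2 + ly^2 + lz^2) and the relative
shape anisotropy

    kappa^2 = 3/2 * (lx^4 + ly^4 + lz^4) / (lx^2 + ly^2 + lz^2)^2 - 1/2

is 0 for spherically symmetric objects and 1 for a line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import Atom, Box, Frame, Trajectory

__all__ = [
    "Cluster", "GyrationTensor", "ShapeMetrics", "RadialDistribution",
    "ResidueDistanceProfile", "find_clusters", "gyration_tensor",
    "shape_metrics", "shape_timeseries", "residue_com_distances",
    "pair_distribution",
]


@dataclass
class Cluster:
    """One connected aggregate in one frame, with unwrapped coordinates."""

    atom_indices: np.ndarray
    molecule_ids: set
    center: np.ndarray          # geometric center of unwrapped coords, A
    frame_index: int
    unwrapped_positions: np.ndarray  # aligned with atom_indices

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass(frozen=True)
class GyrationTensor:
    components: np.ndarray  # 3x3 symmetric, A^2
    origin: np.ndarray      # center used, A

    def __post_init__(self):
        S = np.asarray(self.components, dtype=float)
        if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("gyration tensor must be a symmetric 3x3 matrix")


@dataclass(frozen=True)
class ShapeMetrics:
    principal_moments: tuple[float, float, float]  # descending, A^2
    rg: float       # A
    kappa2: float   # dimensionless in [0, 1]


@dataclass
class RadialDistribution:
    r: np.ndarray        # bin centers, A
    g: np.ndarray        # dimensionless
    counts: np.ndarray   # raw pair counts per bin (summed over frames)
    dr: float

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.r, self.g]),
                   header="r[A]  g(r)", fmt="%.8g")


@dataclass
class ResidueDistanceProfile:
    """Per-residue COM distance to the aggregate COM, peptide-mean removed."""

    residue_names: list[str]
    classes: list[str]                  # hydrophilic / hydrophobic per residue
    relative_distance: np.ndarray       # mean over replicate peptides, A
    sd: np.ndarray                      # SD over replicate peptides, A
    per_peptide: np.ndarray             # (n_peptides, n_residues), A
    class_means: dict[str, float]       # mean relative distance per class

    @property
    def class_separation(self) -> float:
        """Hydrophilic-minus-hydrophobic mean relative distance, A."""
        return self.class_means["hydrophilic"] - self.class_means["hydrophobic"]


# ---------------------------------------------------------------------------
# clustering


def _pairs_within(positions: np.ndarray, box: Box, cutoff: float) -> np.ndarray:
    """(n_pairs, 2) index pairs with (minimum-image) distance < cutoff."""
    if box.fully_periodic:
        L = np.array(box.lengths)
        if cutoff >= L.min() / 2:
            raise ValueError(
                f"cutoff {cutoff} A must be below half the smallest box "
                f"length ({L.min() / 2:.3f} A) for the minimum image to be valid"
            )
        tree = cKDTree(np.mod(positions, L), boxsize=L)
    else:
        tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def find_clusters(
    trajectory_or_topology,
    frame: Frame | int,
    selection: np.ndarray | None = None,
    cutoff: float = 4.5,
    linkage_atoms: str = "heavy",
) -> list[Cluster]:
    """Single-linkage molecular clusters in one frame.

    Two molecules are linked when any pair of qualifying atoms (all atoms
    or heavy atoms only) lies within ``cutoff`` under the minimum-image
    convention.  Each returned cluster's coordinates are unwrapped so the
    aggregate is spatially contiguous; clusters come back largest-first.
    """
    if isinstance(trajectory_or_topology, Trajectory):
        topology = trajectory_or_topology.topology
        if isinstance(frame, (int, np.integer)):
            frame_index = int(frame)
            frame = trajectory_or_topology.frames[frame_index]
        else:
            frame_index = 0
    else:
        topology = trajectory_or_topology
        frame_index = 0
    if not isinstance(frame, Frame):
        raise TypeError("frame must be a Frame or a frame index into a Trajectory")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if linkage_atoms not in {"heavy", "all"}:
        raise ValueError("linkage_atoms must be 'heavy' or 'all'")

    if selection is None:
        selection = np.arange(len(topology))
    selection = np.asarray(selection, dtype=int)
    atoms = [topology[i] for i in selection]
    box = frame.box

    # make every molecule whole relative to its first selected atom
    pos = frame.positions[selection].copy()
    mol_of = np.array([a.molecule_id for a in atoms])
    mols, mol_inverse = np.unique(mol_of, return_inverse=True)
    for m in range(len(mols)):
        members = np.where(mol_inverse == m)[0]
        anchor = pos[members[0]]
        pos[members] = anchor + box.minimum_image(pos[members] - anchor)

    qualifies = np.ones(len(atoms), dtype=bool)
    if linkage_atoms == "heavy":
        qualifies = np.array([a.element != "H" for a in atoms])
    qidx = np.where(qualifies)[0]
    pairs = _pairs_within(pos[qidx], box, cutoff)
    a_loc, b_loc = qidx[pairs[:, 0]] if len(pairs) else np.array([], dtype=int), \
                   qidx[pairs[:, 1]] if len(pairs) else np.array([], dtype=int)

    ma, mb = mol_inverse[a_loc], mol_inverse[b_loc]
    inter = ma != mb
    n_mol = len(mols)
    graph = coo_matrix(
        (np.ones(inter.sum()), (ma[inter], mb[inter])), shape=(n_mol, n_mol)
    )
    n_comp, labels = connected_components(graph, directed=False)

    # one representative linking atom pair per molecule pair, for unwrapping
    edge_rep: dict[tuple[int, int], tuple[int, int]] = {}
    for ia, ib in zip(a_loc[inter], b_loc[inter]):
        key = (min(mol_inverse[ia], mol_inverse[ib]),
               max(mol_inverse[ia], mol_inverse[ib]))
        edge_rep.setdefault(key, (ia, ib))
    adjacency: dict[int, list[tuple[int, int, int]]] = {m: [] for m in range(n_mol)}
    for (m1, m2), (ia, ib) in edge_rep.items():
        adjacency[m1].append((m2, ia, ib))
        adjacency[m2].append((m1, ib, ia))

    clusters: list[Cluster] = []
    for comp in range(n_comp):
        comp_mols = np.where(labels == comp)[0]
        shift = {int(comp_mols[0]): np.zeros(3)}
        stack = [int(comp_mols[0])]
        while stack:  # BFS: place each molecule in the image nearest its link
            m = stack.pop()
            for m2, ia, ib in adjacency[m]:
                if m2 in shift:
                    continue
                pa = pos[ia] + shift[m]
                pb = pos[ib]
                if box.fully_periodic:
                    L = np.array(box.lengths)
                    n_img = np.round((pa - pb) / L)
                    shift[m2] = n_img * L
                else:
                    shift[m2] = np.zeros(3)
                stack.append(m2)
        member_mask = np.isin(mol_inverse, comp_mols)
        member_loc = np.where(member_mask)[0]
        unwrapped = pos[member_loc] + np.stack(
            [shift[int(mol_inverse[i])] for i in member_loc]
        )
        clusters.append(Cluster(
            atom_indices=selection[member_loc],
            molecule_ids={int(mols[m]) for m in comp_mols},
            center=unwrapped.mean(axis=0),
            frame_index=frame_index,
            unwrapped_positions=unwrapped,
        ))
    clusters.sort(key=lambda c: c.n_atoms, reverse=True)
    return clusters


def clusters_to_frame(clusters: list[Cluster], trajectory: Trajectory) -> pd.DataFrame:
    """Cluster assignments as a (frame, molecule_id, cluster_id) table."""
    rows = []
    for cid, c in enumerate(clusters):
        for m in sorted(c.molecule_ids):
            rows.append({"frame": c.frame_index, "molecule_id": m, "cluster_id": cid})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gyration tensor and shape


def gyration_tensor(
    positions: np.ndarray,
    weights: np.ndarray | None = None,
) -> GyrationTensor:
    """Second-moment (gyration) tensor about the (same-weighting) center.

    ``weights=None`` gives the uniform-weight tensor; pass masses for the
    mass-weighted variant.  Coordinates must already be unwrapped
    (cluster-contiguous).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3 or len(positions) == 0:
        raise ValueError("positions must be a non-empty (N, 3) array")
    if weights is None:
        w = np.ones(len(positions))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(positions),) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    center = (w[:, None] * positions).sum(axis=0) / w.sum()
    d = positions - center
    S = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w.sum()
    return GyrationTensor(components=S, origin=center)


def shape_metrics(tensor: GyrationTensor) -> ShapeMetrics:
    """Principal moments, Rg and relative anisotropy from a gyration tensor."""
    moments = np.linalg.eigvalsh(tensor.components)[::-1]
    moments = np.clip(moments, 0.0, None)  # PSD up to round-off
    tr = moments.sum()
    rg = float(np.sqrt(tr))
    if tr == 0.0:
        kappa2 = 0.0
    else:
        m = moments / moments.max()  # scale out to avoid over/underflow
        kappa2 = float(1.5 * np.sum(m ** 2) / m.sum() ** 2 - 0.5)
        kappa2 = min(max(kappa2, 0.0), 1.0)
    return ShapeMetrics(principal_moments=tuple(float(m) for m in moments),
                        rg=rg, kappa2=kappa2)


def shape_timeseries(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    weighting: str = "uniform",
    cutoff: float = 4.5,
    linkage_atoms: str = "heavy",
) -> pd.DataFrame:
    """Per-frame Rg and kappa^2 of the selected aggregate.

    In periodic boxes the selection is unwrapped per frame through the
    cluster machinery (largest cluster used if the selection splits);
    columns: time_ps, Rg_A, kappa2, lambda1..3_A2.  Time means/SDs are
    stored in ``df.attrs['mean']`` / ``df.attrs['sd']``.
    """
    if weighting not in {"uniform", "mass"}:
        raise ValueError("weighting must be 'uniform' or 'mass'")
    if selection is None:
        selection = np.arange(trajectory.n_atoms)
    selection = np.asarray(selection, dtype=int)
    masses = trajectory.masses

    rows = []
    for k, fr in enumerate(trajectory.frames):
        if fr.box.fully_periodic:
            clusters = find_clusters(trajectory.topology, fr, selection,
                                     cutoff=cutoff, linkage_atoms=linkage_atoms)
            clusters[0].frame_index = k
            pos = clusters[0].unwrapped_positions
            idx = clusters[0].atom_indices
        else:
            pos = fr.positions[selection]
            idx = selection
        w = masses[idx] if weighting == "mass" else None
        sm = shape_metrics(gyration_tensor(pos, w))
        rows.append({"time_ps": fr.time, "Rg_A": sm.rg, "kappa2": sm.kappa2,
                     "lambda1_A2": sm.principal_moments[0],
                     "lambda2_A2": sm.principal_moments[1],
                     "lambda3_A2": sm.principal_moments[2]})
    df = pd.DataFrame(rows)
    df.attrs["mean"] = {"Rg_A": float(df["Rg_A"].mean()),
                        "kappa2": float(df["kappa2"].mean())}
    df.attrs["sd"] = {"Rg_A": float(df["Rg_A"].std(ddof=0)),
                      "kappa2": float(df["kappa2"].std(ddof=0))}
    return df


# ---------------------------------------------------------------------------
# residue COM distance profile


def residue_com_distances(
    trajectory: Trajectory,
    cluster: Cluster,
    peptide_molecule_ids: set[int],
    classify,
) -> ResidueDistanceProfile:
    """Residue-COM distances to the aggregate COM, peptide-mean removed.

    For each peptide molecule the distance of every residue's
    (mass-weighted) COM to the aggregate's mass-weighted COM is computed
    and the unweighted mean over that peptide's residues subtracted, so
    the values of each peptide sum to zero.  Replicate peptides are
    averaged; residues are binned into hydrophilic (charged + polar) and
    hydrophobic classes via ``classify`` (a residue_name -> class
    callable, e.g. :func:`amphitraj.conformation.residue_class3`).
    """
    missing = peptide_molecule_ids - cluster.molecule_ids
    if missing:
        raise ValueError(f"peptide molecules {sorted(missing)} are not part of "
                         f"the aggregate (members: {sorted(cluster.molecule_ids)})")
    top = trajectory.topology
    masses = trajectory.masses
    pos_of = {int(i): p for i, p in zip(cluster.atom_indices,
                                        cluster.unwrapped_positions)}
    m_all = masses[cluster.atom_indices]
    com_aggregate = (m_all[:, None] * cluster.unwrapped_positions).sum(axis=0) / m_all.sum()

    per_peptide = []
    residue_names: list[str] | None = None
    for mol in sorted(peptide_molecule_ids):
        atoms = [a for a in top if a.molecule_id == mol and a.index in pos_of]
        res_ids = sorted({a.residue_index for a in atoms})
        names, dists = [], []
        for ri in res_ids:
            res_atoms = [a for a in atoms if a.residue_index == ri]
            w = np.array([a.mass for a in res_atoms])
            p = np.stack([pos_of[a.index] for a in res_atoms])
            com = (w[:, None] * p).sum(axis=0) / w.sum()
            names.append(res_atoms[0].residue_name)
            dists.append(float(np.linalg.norm(com - com_aggregate)))
        dists = np.asarray(dists)
        per_peptide.append(dists - dists.mean())
        if residue_names is None:
            residue_names = names
        elif names != residue_names:
            raise ValueError("replicate peptides have differing residue sequences")
    per_peptide = np.stack(per_peptide)

    classes = ["hydrophobic" if classify(n) == "hydrophobic" else "hydrophilic"
               for n in residue_names]
    rel = per_peptide.mean(axis=0)
    sd = per_peptide.std(axis=0, ddof=1) if len(per_peptide) > 1 \
        else np.zeros_like(rel)
    class_means = {}
    for cls in ("hydrophilic", "hydrophobic"):
        mask = np.array([c == cls for c in classes])
        class_means[cls] = float(rel[mask].mean()) if mask.any() else float("nan")
    return ResidueDistanceProfile(
        residue_names=residue_names, classes=classes, relative_distance=rel,
        sd=sd, per_peptide=per_peptide, class_means=class_means)


# ---------------------------------------------------------------------------
# pair distribution function


def pair_distribution(
    trajectory: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    r_max: float,
    dr: float,
) -> RadialDistribution:
    """g(r) between two selections, minimum-image, frame-averaged.

    Normalisation: g(r) = <n_ab(r, r+dr)> / (4 pi r^2 dr rho_b) with the
    partner density rho_b taken from each frame's instantaneous box
    volume; self pairs are excluded when the selections overlap.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("selections must be non-empty")
    if dr <= 0:
        raise ValueError("dr must be > 0")
    n_bins = int(np.ceil(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    counts = np.zeros(n_bins)
    norm = 0.0

    for fr in trajectory.frames:
        box = fr.box
        if box.fully_periodic:
            L = np.array(box.lengths)
            if r_max > L.min() / 2:
                raise ValueError(
                    f"r_max {r_max} A exceeds half the smallest box length "
                    f"({L.min() / 2:.3f} A)")
            pa = np.mod(fr.positions[sel_a], L)
            pb = np.mod(fr.positions[sel_b], L)
            tree_a = cKDTree(pa, boxsize=L)
            tree_b = cKDTree(pb, boxsize=L)
            volume = box.volume
        else:
            tree_a = cKDTree(fr.positions[sel_a])
            tree_b = cKDTree(fr.positions[sel_b])
            span = fr.positions.max(axis=0) - fr.positions.min(axis=0)
            volume = float(np.prod(np.maximum(span, 1e-9)))
        # self pairs (i == j when selections overlap) sit at d = 0 and are
        # captured by the cumulative count at the r = 0 edge, so the
        # per-bin differences exclude them automatically
        cum = tree_a.count_neighbors(tree_b, edges)
        counts += np.diff(cum).astype(float)
        rho_b = len(sel_b) / volume
        norm += len(sel_a) * rho_b

    centers = edges[:-1] + dr / 2
    shell = 4.0 * np.pi * centers ** 2 * dr
    g = counts / (shell * norm)
    return RadialDistribution(r=centers, g=g, counts=counts, dr=dr)
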