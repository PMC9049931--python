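"""Topology/trajectory data model and coordinate-file I/O.

Internal conventions: coordinates in Angstrom everywhere (GRO nm values
are converted on read), 0-based atom/residue indices internally, 1-based
only at file boundaries, orthorhombic periodic boxes only.

File reading and writing for the standard formats (PDB, GRO, XYZ) is
delegated to MDAnalysis; the LAMMPS-style text dump has a dedicated
reader with strict error reporting.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .elements import (
    UnknownElementError,
    element_from_atom_name,
    element_mass,
    element_number,
    normalize_symbol,
)

__all__ = [
    "Atom", "Box", "Frame", "Trajectory",
    "read_structure", "read_dump", "write_structure",
]


@dataclass(frozen=True)
class Atom:
    """One atom (or coarse bead) of the topology.

    ``electron_count`` is the neutral-atom Z, which serves as the
    q-independent X-ray scattering length; ``mass`` feeds the
    mass-weighted analyses (COM distances, entropy).
    """

    index: int
    name: str
    element: str
    mass: float
    electron_count: int
    residue_index: int = 0
    residue_name: str = "UNK"
    molecule_id: int = 0
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be > 0, got {self.mass}")
        if self.electron_count < 1:
            raise ValueError(
                f"atom {self.index}: electron_count must be >= 1, got {self.electron_count}"
            )

    @classmethod
    def from_element(cls, index: int, element: str, **kwargs) -> "Atom":
        """Build an atom with mass/electron count from the periodic table."""
        sym = normalize_symbol(element)
        kwargs.setdefault("name", sym)
        return cls(index=index, element=sym, mass=element_mass(sym),
                   electron_count=element_number(sym), **kwargs)


@dataclass(frozen=True)
class Box:
    """Orthorhombic simulation cell (lengths in Angstrom)."""

    lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        if len(self.lengths) != 3 or len(self.periodic) != 3:
            raise ValueError("Box needs 3 lengths and 3 periodic flags")
        for L, p in zip(self.lengths, self.periodic):
            if p and L <= 0:
                raise ValueError(f"periodic box length must be > 0, got {L}")

    @property
    def fully_periodic(self) -> bool:
        return all(self.periodic)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @classmethod
    def nonperiodic(cls) -> "Box":
        return cls(lengths=(0.0, 0.0, 0.0), periodic=(False, False, False))

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        d = np.array(d, dtype=float, copy=True)
        for ax in range(3):
            if self.periodic[ax]:
                L = self.lengths[ax]
                d[..., ax] -= L * np.round(d[..., ax] / L)
        return d

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) on each periodic axis."""
        pos = np.array(pos, dtype=float, copy=True)
        for ax in range(3):
            if self.periodic[ax]:
                pos[..., ax] %= self.lengths[ax]
        return pos


@dataclass
class Frame:
    """Coordinates of one snapshot (N x 3, Angstrom) plus box and time."""

    positions: np.ndarray
    box: Box
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Ordered topology plus ordered frames with strictly increasing times."""

    topology: list[Atom]
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        n = len(self.topology)
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {fr.n_atoms} atoms, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def frame_spacing(self) -> float:
        """Median inter-frame spacing in ps (0 for single-frame data)."""
        t = self.times
        return float(np.median(np.diff(t))) if len(t) > 1 else 0.0

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    @property
    def electron_counts(self) -> np.ndarray:
        return np.array([a.electron_count for a in self.topology], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.topology]

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.topology])

    def coordinates(self) -> np.ndarray:
        """(n_frames, N, 3) stacked coordinate array."""
        return np.stack([fr.positions for fr in self.frames])


# ---------------------------------------------------------------------------
# reading


_CHAIN_SYMBOLS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _box_from_dimensions(dims) -> Box:
    if dims is None or not np.any(np.asarray(dims)[:3] > 0):
        return Box.nonperiodic()
    dims = np.asarray(dims, dtype=float)
    lx, ly, lz = dims[:3]
    alpha, beta, gamma = dims[3:6] if dims.size >= 6 else (90.0, 90.0, 90.0)
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise ValueError(
            f"only orthorhombic boxes are supported, got angles "
            f"({alpha:.2f}, {beta:.2f}, {gamma:.2f})"
        )
    return Box(lengths=(float(lx), float(ly), float(lz)))


def _topology_from_universe(u, fmt: str) -> list[Atom]:
    n = len(u.atoms)
    names = u.atoms.names if hasattr(u.atoms, "names") else [""] * n
    try:
        resnames = u.atoms.resnames
    except AttributeError:
        resnames = ["UNK"] * n
    try:
        resindices = u.atoms.resindices
    except AttributeError:
        resindices = np.zeros(n, dtype=int)

    # element symbols: explicit columns first, atom-name inference second
    elements: list[str] = []
    explicit = getattr(u.atoms, "elements", None)
    for i in range(n):
        sym = ""
        if explicit is not None:
            sym = str(explicit[i]).strip()
        if sym:
            sym = normalize_symbol(sym)
            if element_mass(sym) <= 0:  # raises UnknownElementError if unknown
                raise UnknownElementError(sym)
        else:
            sym = element_from_atom_name(str(names[i]), str(resnames[i]))
        elements.append(sym)

    # molecule ids: PDB chains in order of first appearance; GRO residues
    if fmt == "PDB":
        try:
            chains = u.atoms.chainIDs
        except AttributeError:
            chains = [""] * n
        seen: dict[str, int] = {}
        mol_ids = []
        for c in chains:
            key = str(c)
            if key not in seen:
                seen[key] = len(seen)
            mol_ids.append(seen[key])
    elif fmt == "GRO":
        mol_ids = list(np.asarray(resindices, dtype=int))
    else:
        mol_ids = [0] * n

    atoms = []
    for i in range(n):
        atoms.append(Atom(
            index=i,
            name=str(names[i]) if str(names[i]) else elements[i],
            element=elements[i],
            mass=element_mass(elements[i]),
            electron_count=element_number(elements[i]),
            residue_index=int(resindices[i]),
            residue_name=str(resnames[i]),
            molecule_id=int(mol_ids[i]),
        ))
    return atoms


def read_structure(path, format: str | None = None) -> Trajectory:
    """Read a PDB / GRO / XYZ file into a :class:`Trajectory`.

    Elements are taken from explicit columns when present, otherwise
    inferred from atom names; masses and electron counts come from the
    built-in periodic table.  Multi-model PDB files yield multiple
    frames; XYZ files are flagged non-periodic.
    """
    import MDAnalysis as mda

    path = str(path)
    fmt = (format or path.rsplit(".", 1)[-1]).upper()
    if fmt not in {"PDB", "GRO", "XYZ"}:
        raise ValueError(f"unsupported structure format {fmt!r}")

    # multi-model PDB: MDAnalysis only attaches CRYST1 dimensions to
    # single-frame reads, so keep the header record as a fallback
    header_box = None
    if fmt == "PDB":
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    vals = [float(line[6 + 9 * i:15 + 9 * i]) for i in range(3)]
                    angles = [float(line[33 + 7 * i:40 + 7 * i]) for i in range(3)]
                    if not np.allclose(vals, 1.0):  # 1,1,1 = "no box" placeholder
                        header_box = _box_from_dimensions(vals + angles)
                    break
                if line.startswith(("ATOM", "HETATM", "MODEL")):
                    break

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path, format=fmt, topology_format=fmt)
        topology = _topology_from_universe(u, fmt)
        frames = []
        for k, ts in enumerate(u.trajectory):
            if fmt == "XYZ":
                box = Box.nonperiodic()
            else:
                box = _box_from_dimensions(ts.dimensions)
                if not box.fully_periodic and header_box is not None:
                    box = header_box
            t = float(ts.time) if np.isfinite(ts.time) and ts.time > 0 else float(k)
            frames.append(Frame(positions=ts.positions.astype(float).copy(),
                                box=box, time=t))
    # some readers report identical times for all models; fall back to index
    times = [fr.time for fr in frames]
    if len(set(times)) != len(times):
        for k, fr in enumerate(frames):
            fr.time = float(k)
    return Trajectory(topology=topology, frames=frames)


def read_dump(path, topology: list[Atom]) -> Trajectory:
    """Read a LAMMPS-style text dump (ITEM: TIMESTEP / BOX BOUNDS / ATOMS).

    Atom lines must carry id and x/y/z (or xs/ys/zs scaled) columns; atoms
    are re-sorted by id so the frame order matches ``topology``.  Times
    are the dump timestep numbers (interpreted as ps).
    """
    n_top = len(topology)
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()

    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("ITEM: TIMESTEP"):
            raise ValueError(f"unexpected dump content at line {i + 1}: {line!r}")
        timestep = int(lines[i + 1].strip())
        i += 2

        def _fail(msg: str):
            raise ValueError(f"timestep {timestep}: {msg}")

        if i >= n_lines or not lines[i].startswith("ITEM: NUMBER OF ATOMS"):
            _fail("missing 'ITEM: NUMBER OF ATOMS'")
        n_atoms = int(lines[i + 1].strip())
        if n_atoms != n_top:
            _fail(f"dump has {n_atoms} atoms, topology has {n_top}")
        i += 2

        if i >= n_lines or not lines[i].startswith("ITEM: BOX BOUNDS"):
            _fail("missing 'ITEM: BOX BOUNDS'")
        if "xy" in lines[i]:
            _fail("triclinic box bounds are not supported (orthorhombic only)")
        bounds = []
        for ax in range(3):
            parts = lines[i + 1 + ax].split()
            lo, hi = float(parts[0]), float(parts[1])
            bounds.append((lo, hi))
        box = Box(lengths=tuple(hi - lo for lo, hi in bounds))
        i += 4

        if i >= n_lines or not lines[i].startswith("ITEM: ATOMS"):
            _fail("missing 'ITEM: ATOMS'")
        cols = lines[i].split()[2:]
        col_index = {c: k for k, c in enumerate(cols)}
        if "id" not in col_index:
            _fail("dump has no 'id' column")
        if all(c in col_index for c in ("x", "y", "z")):
            xyz_cols = ("x", "y", "z")
            scaled = False
        elif all(c in col_index for c in ("xs", "ys", "zs")):
            xyz_cols = ("xs", "ys", "zs")
            scaled = True
        else:
            _fail("dump has no x/y/z (or xs/ys/zs) coordinate columns")
        i += 1

        if i + n_atoms > n_lines:
            _fail(f"truncated frame: expected {n_atoms} atom lines, "
                  f"found {n_lines - i}")
        pos = np.empty((n_atoms, 3))
        seen = np.zeros(n_atoms, dtype=bool)
        origin = np.array([lo for lo, _ in bounds])
        for row in range(n_atoms):
            parts = lines[i + row].split()
            if len(parts) < len(cols):
                _fail(f"short atom line {i + row + 1}")
            atom_id = int(float(parts[col_index["id"]]))
            if not (1 <= atom_id <= n_atoms):
                _fail(f"atom id {atom_id} out of range 1..{n_atoms}")
            xyz = np.array([float(parts[col_index[c]]) for c in xyz_cols])
            if scaled:
                xyz = origin + xyz * np.array(box.lengths)
            pos[atom_id - 1] = xyz
            seen[atom_id - 1] = True
        if not seen.all():
            _fail("duplicate or missing atom ids")
        i += n_atoms
        frames.append(Frame(positions=pos, box=box, time=float(timestep)))

    if not frames:
        raise ValueError("dump file contains no frames")
    return Trajectory(topology=list(topology), frames=frames)


# ---------------------------------------------------------------------------
# writing


def write_structure(trajectory: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as (multi-model) PDB or XYZ via MDAnalysis.

    PDB encodes ``molecule_id`` as the chain identifier (up to 62
    distinct molecules); XYZ stores element symbols and coordinates only.
    """
    import MDAnalysis as mda

    path = str(path)
    fmt = (format or path.rsplit(".", 1)[-1]).upper()
    if fmt not in {"PDB", "XYZ"}:
        raise ValueError(f"unsupported output format {fmt!r}")

    top = trajectory.topology
    n = len(top)
    resindices = np.array([a.residue_index for a in top])
    _, atom_resindex = np.unique(resindices, return_inverse=True)
    n_res = int(atom_resindex.max()) + 1 if n else 0

    mol_ids = sorted({a.molecule_id for a in top})
    if fmt == "PDB" and len(mol_ids) > len(_CHAIN_SYMBOLS):
        raise ValueError(
            f"PDB chain IDs can encode at most {len(_CHAIN_SYMBOLS)} molecules, "
            f"got {len(mol_ids)}"
        )
    chain_of = {m: _CHAIN_SYMBOLS[k % len(_CHAIN_SYMBOLS)] for k, m in enumerate(mol_ids)}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=atom_resindex,
                               residue_segindex=np.zeros(n_res, dtype=int),
                               trajectory=True)
        u.add_TopologyAttr("names", [a.name for a in top])
        u.add_TopologyAttr("elements", [a.element for a in top])
        u.add_TopologyAttr("masses", [a.mass for a in top])
        u.add_TopologyAttr("chainIDs", [chain_of[a.molecule_id] for a in top])
        resnames = [None] * n_res
        resids = [None] * n_res
        for a, ri in zip(top, atom_resindex):
            resnames[ri] = a.residue_name
            resids[ri] = a.residue_index + 1
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)

        box0 = trajectory.frames[0].box
        with mda.Writer(path, n_atoms=n, multiframe=len(trajectory.frames) > 1) as w:
            for fr in trajectory.frames:
                u.atoms.positions = fr.positions
                if fr.box.fully_periodic:
                    u.dimensions = [*fr.box.lengths, 90.0, 90.0, 90.0]
                w.write(u.atoms)
        del box0
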