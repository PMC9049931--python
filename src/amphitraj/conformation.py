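"""Peptide conformation: torsions, hydrogen bonds, secondary structure,
Kabsch superposition and RMSD, and sequence composition.

Secondary structure is assigned from backbone hydrogen-bond energies and
torsion angles, in the spirit of STRIDE/DSSP.  The hydrogen-bond energy
is the Kabsch-Sander electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond existing when E < -0.5 kcal/mol (|i - j| < 2 pairs excluded).  A
residue is alpha-helical (H) when it is strictly enclosed by two
consecutive i -> i+4 hydrogen-bonded turns and its (phi, psi) lie in the
helical window; exact parity with the STRIDE program's fitted empirical
surfaces is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Frame, Trajectory

__all__ = [
    "BackboneGeometry", "SecondaryStructureSeries", "ResidueClassification",
    "backbone_torsions", "hbond_energy", "assign_secondary_structure",
    "helicity", "superpose", "rmsd_series", "classify_residues",
    "dihedral", "LL37_SEQUENCE", "residue_class", "residue_class3",
    "THREE_TO_ONE",
]

#: human cathelicidin LL-37 (one-letter code)
LL37_SEQUENCE = "LLGDFFRKSKEKIGKEFKRIVQRIKDFLRNLVPRTES"

HELICAL_PHI = (-100.0, -30.0)
HELICAL_PSI = (-80.0, -5.0)
HBOND_CUTOFF_KCAL = -0.5

# residue classes at pH 7
_CHARGED = set("DEKRH")
_POLAR = set("STNQCY")
_HYDROPHOBIC = set("AVLIPFMWG")
_BASIC = set("KRH")
_ACIDIC = set("DE")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def residue_class(letter: str) -> str:
    """'charged' / 'polar' / 'hydrophobic' for a one-letter residue code."""
    if letter in _CHARGED:
        return "charged"
    if letter in _POLAR:
        return "polar"
    if letter in _HYDROPHOBIC:
        return "hydrophobic"
    raise ValueError(f"unknown residue letter {letter!r}")


def residue_class3(resname: str) -> str:
    """Class of a 3-letter residue name; unknown names count hydrophilic."""
    one = THREE_TO_ONE.get(resname.strip().upper())
    return residue_class(one) if one else "polar"


# ---------------------------------------------------------------------------
# geometry primitives


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign, range (-180, 180]."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


@dataclass
class BackboneGeometry:
    """Per-residue backbone coordinates and phi/psi torsions (degrees).

    Torsions undefined at the termini are NaN.  ``h`` holds the amide
    hydrogen positions (geometrically rebuilt when absent); the first
    residue carries no donor hydrogen (NaN row).
    """

    residue_names: list[str]
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)


def _backbone_arrays(trajectory: Trajectory, frame: Frame, residue_indices):
    """Collect N/CA/C/O(/H) coordinates per residue, by atom name."""
    top = trajectory.topology
    per_res: dict[int, dict[str, np.ndarray]] = {int(r): {} for r in residue_indices}
    names: dict[int, str] = {}
    for a in top:
        if a.residue_index in per_res and a.name in {"N", "CA", "C", "O", "H", "HN"}:
            key = "H" if a.name == "HN" else a.name
            per_res[a.residue_index][key] = frame.positions[a.index]
            names[a.residue_index] = a.residue_name
    return per_res, names


def backbone_torsions(
    trajectory: Trajectory,
    frame: Frame | int,
    residue_indices=None,
) -> BackboneGeometry:
    """Backbone coordinates and phi/psi for a peptide in one frame.

    phi_i is C_{i-1}-N_i-CA_i-C_i, psi_i is N_i-CA_i-C_i-N_{i+1};
    termini where a neighbour is missing are flagged NaN.
    """
    if isinstance(frame, (int, np.integer)):
        frame = trajectory.frames[int(frame)]
    if residue_indices is None:
        residue_indices = sorted({a.residue_index for a in trajectory.topology})
    residue_indices = [int(r) for r in residue_indices]
    per_res, resnames = _backbone_arrays(trajectory, frame, residue_indices)

    n_res = len(residue_indices)
    arr = {k: np.full((n_res, 3), np.nan) for k in ("N", "CA", "C", "O", "H")}
    for i, ri in enumerate(residue_indices):
        atoms = per_res[ri]
        for k in ("N", "CA", "C"):
            if k not in atoms:
                raise ValueError(
                    f"residue {ri} ({resnames.get(ri, '?')}) is missing "
                    f"backbone atom {k}")
            arr[k][i] = atoms[k]
        if "O" in atoms:
            arr["O"][i] = atoms["O"]
        if "H" in atoms:
            arr["H"][i] = atoms["H"]

    # geometric amide H: 1.0 A from N, opposite the C(i-1)/CA bisector
    for i in range(1, n_res):
        if np.any(np.isnan(arr["H"][i])):
            u1 = arr["N"][i] - arr["C"][i - 1]
            u2 = arr["N"][i] - arr["CA"][i]
            u = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            arr["H"][i] = arr["N"][i] + u / np.linalg.norm(u)

    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    for i in range(n_res):
        if i > 0:
            phi[i] = dihedral(arr["C"][i - 1], arr["N"][i], arr["CA"][i], arr["C"][i])
        if i < n_res - 1:
            psi[i] = dihedral(arr["N"][i], arr["CA"][i], arr["C"][i], arr["N"][i + 1])
    return BackboneGeometry(
        residue_names=[resnames[r] for r in residue_indices],
        n=arr["N"], ca=arr["CA"], c=arr["C"], o=arr["O"], h=arr["H"],
        phi=phi, psi=psi)


def hbond_energy(geometry: BackboneGeometry, donor: int, acceptor: int) -> float:
    """Kabsch-Sander energy (kcal/mol) of the N-H(donor)...O=C(acceptor) pair.

    Returns 0 (no bond) for |donor - acceptor| < 2, for a donor without
    an amide hydrogen, and for overlapping atoms (< 0.1 A).
    """
    if abs(donor - acceptor) < 2:
        return 0.0
    Np, Hp = geometry.n[donor], geometry.h[donor]
    Cp, Op = geometry.c[acceptor], geometry.o[acceptor]
    if np.any(np.isnan(Hp)) or np.any(np.isnan(Op)):
        return 0.0
    r_on = np.linalg.norm(Op - Np)
    r_ch = np.linalg.norm(Cp - Hp)
    r_oh = np.linalg.norm(Op - Hp)
    r_cn = np.linalg.norm(Cp - Np)
    if min(r_on, r_ch, r_oh, r_cn) < 0.1:
        return 0.0
    return 0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_set(geometry: BackboneGeometry) -> set[tuple[int, int]]:
    """(acceptor, donor) residue pairs with a Kabsch-Sander hydrogen bond."""
    n = geometry.n_residues
    bonds = set()
    for acc in range(n):
        for don in range(n):
            if abs(don - acc) < 2:
                continue
            if hbond_energy(geometry, don, acc) < HBOND_CUTOFF_KCAL:
                bonds.add((acc, don))
    return bonds


@dataclass
class SecondaryStructureSeries:
    """frames x residues matrix of labels in {H, G, E, T, C}."""

    labels: np.ndarray      # dtype '<U1'
    times: np.ndarray       # ps
    residue_names: list[str]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]

    def as_strings(self) -> list[str]:
        """One string per frame, one character per residue."""
        return ["".join(row) for row in self.labels]


def _in_window(value: float, window: tuple[float, float]) -> bool:
    return not np.isnan(value) and window[0] <= value <= window[1]


def assign_frame_secondary_structure(geometry: BackboneGeometry) -> np.ndarray:
    """H/G/E/T/C labels for one frame (priority H > G > E > T > C)."""
    n = geometry.n_residues
    bonds = _hbond_set(geometry)
    turn4 = np.array([(i, i + 4) in bonds for i in range(n)])  # CO(i)->NH(i+4)
    turn3 = np.array([(i, i + 3) in bonds for i in range(n)])

    helical = np.array([
        _in_window(geometry.phi[i], HELICAL_PHI)
        and _in_window(geometry.psi[i], HELICAL_PSI)
        for i in range(n)
    ])

    labels = np.full(n, "C", dtype="<U1")

    # turns first (lowest priority): interior of any isolated 3/4-turn
    for i in range(n):
        if turn4[i] and not ((i > 0 and turn4[i - 1]) or (i + 1 < n and turn4[i + 1])):
            labels[i + 1:i + 4] = "T"
        if turn3[i] and not ((i > 0 and turn3[i - 1]) or (i + 1 < n and turn3[i + 1])):
            labels[i + 1:i + 3] = "T"

    # strand bridges: mutually hydrogen-bonded distant residues
    for i in range(n):
        for j in range(i + 3, n):
            if ((i, j) in bonds and (j, i) in bonds) or \
               ((i - 1, j) in bonds and (j - 1, i) in bonds if i >= 1 and j >= 1 else False):
                labels[i] = "E"
                labels[j] = "E"

    # 3_10: residue enclosed by two consecutive i->i+3 turns
    for i in range(n - 1):
        if turn3[i] and turn3[i + 1]:
            r = i + 2
            if r < n and helical[r]:
                labels[r] = "G"

    # alpha helix: residues strictly enclosed by two consecutive i->i+4 turns
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for r in (i + 2, i + 3):
                if r < n and helical[r]:
                    labels[r] = "H"
    return labels


def assign_secondary_structure(
    trajectory: Trajectory,
    residue_indices=None,
    stride_ps: float | None = None,
) -> SecondaryStructureSeries:
    """Per-frame, per-residue secondary-structure labels.

    ``stride_ps`` sub-samples the trajectory (default: every frame); it
    must be a multiple of the frame spacing.
    """
    times = trajectory.times
    if stride_ps is None or trajectory.n_frames == 1:
        frame_ids = np.arange(trajectory.n_frames)
    else:
        spacing = trajectory.frame_spacing
        step = stride_ps / spacing
        if not np.isclose(step, round(step)):
            raise ValueError(
                f"stride_ps = {stride_ps} is not a multiple of the frame "
                f"spacing ({spacing} ps)")
        frame_ids = np.arange(0, trajectory.n_frames, int(round(step)))

    rows = []
    resnames = None
    for k in frame_ids:
        geo = backbone_torsions(trajectory, int(k), residue_indices)
        rows.append(assign_frame_secondary_structure(geo))
        resnames = geo.residue_names
    return SecondaryStructureSeries(labels=np.stack(rows),
                                    times=times[frame_ids],
                                    residue_names=resnames)


def helicity(series: SecondaryStructureSeries):
    """Fraction of residues labeled H: (mean, population SD, per-frame series)."""
    per_frame = (series.labels == "H").mean(axis=1)
    return float(per_frame.mean()), float(per_frame.std(ddof=0)), per_frame


# ---------------------------------------------------------------------------
# superposition and RMSD


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
    weights: np.ndarray | None = None,
):
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Returns (rotation 3x3, translation 3, rmsd over the fit atoms).  A
    proper rotation is enforced via the determinant sign correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    if len(idx) < 3:
        raise ValueError("need at least 3 fit atoms")
    x = mobile[idx]
    y = reference[idx]
    w = np.ones(len(idx)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()

    xc = (w[:, None] * x).sum(axis=0) / wsum
    yc = (w[:, None] * y).sum(axis=0) / wsum
    x0, y0 = x - xc, y - yc
    H = (w[:, None] * x0).T @ y0
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) fit atom set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    fitted = (R @ x.T).T + t
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - y) ** 2) / wsum))
    return R, t, rmsd


def rmsd_series(
    trajectory: Trajectory,
    selection: np.ndarray,
    reference_frame: int = 0,
    exclude_last: int = 0,
) -> pd.DataFrame:
    """Per-frame RMSD (A) over a selection after Kabsch superposition.

    ``exclude_last`` drops that many trailing atoms of the selection
    (e.g. C-terminal alpha-carbons) from both fit and report.
    """
    selection = np.asarray(selection, dtype=int)
    if exclude_last:
        selection = selection[:-exclude_last]
    if len(selection) < 3:
        raise ValueError("selection (after exclusion) needs >= 3 atoms")
    ref = trajectory.frames[reference_frame].positions[selection]
    rows = []
    for fr in trajectory.frames:
        _, _, r = superpose(fr.positions[selection], ref)
        rows.append({"time_ps": fr.time, "rmsd_A": r, "rmsd_nm": r / 10.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence composition


@dataclass
class ResidueClassification:
    """Residue-class composition of a peptide sequence at pH 7."""

    sequence: str
    classes: list[str]          # charged / polar / hydrophobic per residue
    subcharges: list[str]       # basic / acidic / neutral per residue
    counts: dict[str, int]
    fractions: dict[str, float]         # exact fractions
    percent: dict[str, int]             # rounded to nearest integer
    basic_fraction_of_charged: float
    net_charge: int

    # histidine is counted charged-basic; LL-37 contains none, so the
    # reported percentages are insensitive to that choice
    notes: str = "His counted charged/basic; percentages rounded to integers"


def classify_residues(sequence: str) -> ResidueClassification:
    """Charged/polar/hydrophobic composition and net charge of a sequence."""
    seq = sequence.strip().upper()
    classes = [residue_class(ch) for ch in seq]  # raises on unknown letters
    subcharges = ["basic" if ch in _BASIC else "acidic" if ch in _ACIDIC
                  else "neutral" for ch in seq]
    n = len(seq)
    counts = {cls: classes.count(cls) for cls in ("charged", "polar", "hydrophobic")}
    fractions = {cls: counts[cls] / n for cls in counts}
    percent = {cls: round(100.0 * fractions[cls]) for cls in counts}
    n_basic = subcharges.count("basic")
    n_acidic = subcharges.count("acidic")
    charged = counts["charged"]
    return ResidueClassification(
        sequence=seq, classes=classes, subcharges=subcharges, counts=counts,
        fractions=fractions, percent=percent,
        basic_fraction_of_charged=n_basic / charged if charged else 0.0,
        net_charge=n_basic - n_acidic)
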