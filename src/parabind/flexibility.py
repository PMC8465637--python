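"""Trajectory analytics: superposition, RMSD, fluctuations, B-factors.

Post-processing of coordinate trajectories in the style of MD analysis
toolchains: weighted least-squares rigid-body superposition (proper
rotations only), backbone RMSD time series against the starting structure,
per-residue mass-weighted positional fluctuations about the (iterated) mean
structure, conversion to simulated B-factors via ``B = (8 pi^2 / 3) <dr^2>``,
flexible-region calling, and core-superposed marker displacement between
two frames (the "how far did the wing tip move" measurement).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "SuperpositionResult",
    "FluctuationProfile",
    "FlexibleRegion",
    "B_FACTOR_CONSTANT",
    "superpose",
    "rmsd_series",
    "fluctuation_profile",
    "flexible_regions",
    "displacement",
    "read_trajectory_pdb",
    "write_trajectory_pdb",
    "write_profile_csv",
]

B_FACTOR_CONSTANT = 8.0 * np.pi**2 / 3.0  # B = (8 pi^2 / 3) <dr^2>

# element -> atomic mass (Da); enough for backbone/CA work
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (Angstrom) with residue map and masses."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    residue_ids: np.ndarray  # (n_atoms,)
    masses: np.ndarray  # (n_atoms,) Da
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        n_atoms = self.coords.shape[1]
        if self.residue_ids.shape != (n_atoms,) or self.masses.shape != (n_atoms,):
            raise ValueError("residue_ids and masses must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,): x' = R x + t
    rmsd: float  # Angstrom, weighted, after transform


@dataclass
class FluctuationProfile:
    """Per-residue mean-square fluctuation (Angstrom^2) and B-factor."""

    residue_ids: np.ndarray
    msf: np.ndarray  # <dr^2>, mass-weighted over each residue's atoms
    bfactor: np.ndarray  # (8 pi^2 / 3) * msf
    reference: str = "mean"


@dataclass
class FlexibleRegion:
    start_residue: int
    end_residue: int
    peak_residue: int
    peak_bfactor: float


def superpose(
    reference: np.ndarray, mobile: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Optimal weighted rigid-body superposition of ``mobile`` onto
    ``reference`` (Kabsch algorithm, proper rotation enforced).

    Returns the rotation/translation mapping mobile coordinates as
    ``x' = R x + t`` and the weighted RMSD after the transform,
    ``sqrt(sum w_i |x'_i - ref_i|^2 / sum w_i)``.

    Raises
    ------
    ValueError
        On shape mismatch, fewer than 3 atoms, or degenerate (coincident or
        collinear) reference/mobile point sets, for which the rotation is
        not uniquely determined.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(mobile, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("reference and mobile must both be (n_atoms, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    ca = (w[:, None] * a).sum(axis=0)
    cb = (w[:, None] * b).sum(axis=0)
    ac = a - ca
    bc = b - cb

    for pts in (ac, bc):
        s = np.linalg.svd(np.sqrt(w)[:, None] * pts, compute_uv=False)
        if s[0] <= 1e-12 or s[1] <= 1e-9 * s[0]:
            raise ValueError("degenerate (coincident or collinear) atom set")

    h = bc.T @ (w[:, None] * ac)  # 3x3 covariance, mobile -> reference
    u, _, vt = np.linalg.svd(h.T)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    trans = ca - rot @ cb
    moved = bc @ rot.T + ca
    rmsd = float(np.sqrt((w * np.sum((moved - a) ** 2, axis=1)).sum()))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory, reference: np.ndarray | str = "first"
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) after superposition onto a reference.

    ``reference`` is the first frame by default (the conventional
    "deviation from the starting structure" series) or any supplied
    coordinate array of matching shape.
    """
    ref = traj.coords[0] if isinstance(reference, str) else np.asarray(reference)
    if isinstance(reference, str) and reference != "first":
        raise ValueError(f"unknown reference {reference!r}")
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("reference shape must match the trajectory atoms")
    return np.array(
        [superpose(ref, frame, traj.masses).rmsd for frame in traj.coords]
    )


def _superposed_frames(
    traj: Trajectory, ref: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    w = traj.masses if weights is None else weights
    out = np.empty_like(traj.coords)
    for i, frame in enumerate(traj.coords):
        sp = superpose(ref, frame, w)
        out[i] = frame @ sp.rotation.T + sp.translation
    return out


def _atom_msf(aligned: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean_structure = aligned.mean(axis=0)
    return np.mean(np.sum((aligned - mean_structure) ** 2, axis=2), axis=0), mean_structure


def fluctuation_profile(traj: Trajectory, mean_iterations: int = 2) -> FluctuationProfile:
    """Per-residue mean-square positional fluctuation and simulated B-factor.

    Frames are superposed onto an iteratively refined mean structure
    (``mean_iterations`` passes, starting from the first frame), the
    time-averaged squared deviation ``<dr_i^2>`` is computed per atom,
    mass-weight-averaged within each residue, and converted to a
    crystallographic-style temperature factor ``B = (8 pi^2 / 3) <dr^2>``.

    After the mass-weighted passes the superposition weights are refined to
    ``mass / <dr_i^2>`` (variance-weighted, in the spirit of maximum-
    likelihood superposition): otherwise a strongly mobile region drags the
    rigid-body fit, inflating the apparent fluctuation of the rigid core
    and deflating that of the mobile region.

    Requires at least two frames.
    """
    if traj.n_frames < 2:
        raise ValueError("fluctuations need at least 2 frames")
    ref = traj.coords[0]
    for _ in range(mean_iterations):
        ref = _superposed_frames(traj, ref).mean(axis=0)
    msf_atom, _ = _atom_msf(_superposed_frames(traj, ref))
    # variance-weighted refinement pass
    inv_var = traj.masses / np.maximum(msf_atom, 1e-8)
    aligned = _superposed_frames(traj, ref, weights=inv_var)
    ref = aligned.mean(axis=0)
    aligned = _superposed_frames(traj, ref, weights=inv_var)
    msf_atom, _ = _atom_msf(aligned)

    residues = pd.unique(traj.residue_ids)
    msf = np.empty(len(residues))
    for k, res in enumerate(residues):
        sel = traj.residue_ids == res
        w = traj.masses[sel]
        msf[k] = float(np.average(msf_atom[sel], weights=w))
    return FluctuationProfile(
        residue_ids=np.asarray(residues),
        msf=msf,
        bfactor=B_FACTOR_CONSTANT * msf,
        reference="mean",
    )


def _otsu_threshold(values: np.ndarray) -> float:
    """Exact 1-D two-class (Otsu) split maximizing between-class variance."""
    v = np.sort(values.astype(float))
    n = v.size
    best_t, best_score = v[-1], -np.inf
    csum = np.cumsum(v)
    total = csum[-1]
    for k in range(1, n):  # split: v[:k] low, v[k:] high
        w0, w1 = k / n, (n - k) / n
        mu0 = csum[k - 1] / k
        mu1 = (total - csum[k - 1]) / (n - k)
        score = w0 * w1 * (mu1 - mu0) ** 2
        if score > best_score:
            best_score, best_t = score, 0.5 * (v[k - 1] + v[k])
    return float(best_t)


def flexible_regions(
    profile: FluctuationProfile,
    n_sd: float = 2.0,
    gap_tolerance: int = 2,
    rule: str = "auto",
) -> list[FlexibleRegion]:
    """Call flexible regions as runs of residues with outlying B-factors.

    The primary rule flags residues with ``B > mean + n_sd * SD``.  That
    statistic assumes the flexible residues are a minority; when roughly
    half the chain is mobile the global SD is inflated and nothing exceeds
    mean + 2 SD.  The default ``"auto"`` rule therefore falls back to an
    exact two-class (Otsu) threshold when the outlier rule flags nothing
    but the profile is strongly bimodal (90th percentile > 4x the 10th);
    ``"mean_sd"``
    and ``"otsu"`` select either rule unconditionally.

    Flagged residues separated by at most ``gap_tolerance`` unflagged ones
    are merged into one interval; each interval reports its peak residue.
    A flat profile yields no regions.
    """
    b = profile.bfactor
    if b.size == 0:
        return []
    if rule not in ("auto", "mean_sd", "otsu"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "otsu":
        threshold = _otsu_threshold(b)
    else:
        threshold = float(b.mean() + n_sd * b.std())
    flagged = np.flatnonzero(b > threshold)
    if flagged.size == 0 and rule == "auto":
        p10, p90 = np.percentile(b, [10, 90])
        if p90 > 4.0 * max(p10, 1e-12):
            flagged = np.flatnonzero(b > _otsu_threshold(b))
    if flagged.size == 0:
        return []
    regions: list[FlexibleRegion] = []
    run = [flagged[0]]
    for idx in flagged[1:]:
        if idx - run[-1] <= gap_tolerance + 1:
            run.append(idx)
        else:
            regions.append(_make_region(profile, run))
            run = [idx]
    regions.append(_make_region(profile, run))
    return regions


def _make_region(profile: FluctuationProfile, run: list[int]) -> FlexibleRegion:
    lo, hi = run[0], run[-1]
    segment = slice(lo, hi + 1)
    peak = lo + int(np.argmax(profile.bfactor[segment]))
    return FlexibleRegion(
        start_residue=int(profile.residue_ids[lo]),
        end_residue=int(profile.residue_ids[hi]),
        peak_residue=int(profile.residue_ids[peak]),
        peak_bfactor=float(profile.bfactor[peak]),
    )


def displacement(
    traj: Trajectory,
    marker_residue: int,
    core_residues: Sequence[int] | None = None,
    frame_a: int = 0,
    frame_b: int = -1,
) -> float:
    """Displacement (Angstrom) of a marker residue between two frames after
    superposing frame_b onto frame_a on a stable core selection.

    ``core_residues`` defaults to every residue except the marker.  The
    marker's atoms are averaged (mass-weighted) into one position per frame.
    """
    ids = traj.residue_ids
    if marker_residue not in ids:
        raise ValueError(f"marker residue {marker_residue} not in trajectory")
    core = (
        np.asarray([r for r in pd.unique(ids) if r != marker_residue])
        if core_residues is None
        else np.asarray(core_residues)
    )
    core_sel = np.isin(ids, core)
    if core_sel.sum() < 3:
        raise ValueError("core selection must contain at least 3 atoms")
    a = traj.coords[frame_a]
    b = traj.coords[frame_b]
    sp = superpose(a[core_sel], b[core_sel], traj.masses[core_sel])
    b_fit = b @ sp.rotation.T + sp.translation

    marker_sel = ids == marker_residue
    w = traj.masses[marker_sel]
    pos_a = np.average(a[marker_sel], axis=0, weights=w)
    pos_b = np.average(b_fit[marker_sel], axis=0, weights=w)
    return float(np.linalg.norm(pos_b - pos_a))


# ---------------------------------------------------------------------------
# I/O


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Export as a multi-model CA-only PDB (MODEL/ATOM/ENDMDL records)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    stack.coord = traj.coords.astype(np.float32)
    stack.chain_id = np.full(n_atoms, "A")
    stack.res_id = traj.residue_ids.astype(int)
    stack.res_name = np.full(n_atoms, "ALA")
    stack.atom_name = np.full(n_atoms, "CA")
    stack.element = np.full(n_atoms, "C")
    stack.hetero = np.full(n_atoms, False)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB into a trajectory.

    Masses are assigned from the element column (carbon for CA-only files);
    per-residue masses beyond the element are carried only by the CSV
    trajectory format.
    """
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure()
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    masses = np.array(
        [_ELEMENT_MASSES.get(str(e).upper(), 12.011) for e in stack.element]
    )
    return Trajectory(
        coords=coords, residue_ids=np.asarray(stack.res_id), masses=masses
    )


def write_profile_csv(profile: FluctuationProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "residue": profile.residue_ids,
            "msf_A2": profile.msf,
            "bfactor_A2": profile.bfactor,
        }
    ).to_csv(path, index=False)
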