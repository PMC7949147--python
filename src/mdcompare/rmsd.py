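"""Optimal rigid-body superposition (Kabsch) and time-averaged RMSD.

The superposition minimizing the RMSD between two coordinate sets is
computed from the SVD of the 3x3 cross-covariance matrix, with the
determinant sign fixed so the rotation is always proper.  The
implementation is batched over frames (``numpy`` batched SVD) so whole
trajectories are superposed in one call; this is what the RMSD series and
PCA modules build on.

``time_averaged_rmsd`` is the disruption metric for a structural region:
mean over frames of the per-frame RMSD of a *measure* selection after
superposing each frame on a *fit* selection (reference = frame 0 or the
crystal structure by convention).  No mass weighting by default; pass
``mass_weighted=True`` to weight both the fit and the deviation by atomic
mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Optional

import numpy as np

from .core import AtomSelection, Trajectory
from .errors import MDCompareError, SuperpositionError

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "superpose_frames",
    "rmsd_series",
    "time_averaged_rmsd",
    "write_rmsd_tsv",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform ``x' = rotation @ x + translation`` (mobile -> reference).

    ``rotation`` is a proper orthonormal 3x3 matrix (det +1) and
    ``rmsd_after_fit`` the RMSD over the fit atoms after applying it.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after_fit: float


def _check_fit_coords(coords: np.ndarray) -> None:
    if coords.shape[-2] < 3:
        raise SuperpositionError("superposition requires at least 3 atoms")
    centered = coords - coords.mean(axis=-2, keepdims=True)
    # collinear (or coincident) points leave < 2 significant singular values
    s = np.linalg.svd(centered, compute_uv=False)
    if np.any(s[..., 1] <= 1e-10 * (1.0 + s[..., 0])):
        raise SuperpositionError("degenerate (collinear) fit geometry")


def _batched_rotations(mobile: np.ndarray, reference: np.ndarray,
                       weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Optimal rotations for ``mobile (..., N, 3)`` onto ``reference (N, 3)``.

    Both inputs must already be centered.  Returns matrices ``R`` acting on
    column vectors: ``x' = R @ x``.
    """
    if weights is not None:
        mobile = mobile * weights[:, None]
    cov = np.swapaxes(mobile, -2, -1) @ reference       # (..., 3, 3)
    u, _s, vt = np.linalg.svd(cov)
    det = np.linalg.det(np.swapaxes(vt, -2, -1) @ np.swapaxes(u, -2, -1))
    d = np.ones(cov.shape[:-2] + (3,))
    d[..., 2] = np.sign(det)
    # row-vector form: y = x @ (u * d) @ vt; column form R = (u*d @ vt)^T
    r_row = (u * d[..., None, :]) @ vt
    return np.swapaxes(r_row, -2, -1)


def _weighted_mean(coords: np.ndarray, weights: Optional[np.ndarray]) -> np.ndarray:
    if weights is None:
        return coords.mean(axis=-2, keepdims=True)
    w = weights / weights.sum()
    return np.einsum("...nx,n->...x", coords, w)[..., None, :]


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_selection: Optional[AtomSelection] = None,
                     weights: Optional[np.ndarray] = None) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    ``mobile`` and ``reference`` are ``(N, 3)`` coordinate arrays; if
    ``fit_selection`` is given the transform is fitted on (and the RMSD
    reported over) those atoms only.  Fewer than three fit atoms or a
    collinear arrangement raises :class:`SuperpositionError`.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise MDCompareError("mobile and reference must have equal shapes")
    if fit_selection is not None:
        idx = fit_selection.as_array()
        mob_fit, ref_fit = mobile[idx], reference[idx]
        if weights is not None:
            weights = weights[idx]
    else:
        mob_fit, ref_fit = mobile, reference
    _check_fit_coords(mob_fit)
    _check_fit_coords(ref_fit)

    mob_centroid = _weighted_mean(mob_fit, weights)[0]
    ref_centroid = _weighted_mean(ref_fit, weights)[0]
    rot = _batched_rotations((mob_fit - mob_centroid)[None],
                             ref_fit - ref_centroid, weights)[0]
    translation = ref_centroid - rot @ mob_centroid
    fitted = (mob_fit @ rot.T) + translation
    diff2 = ((fitted - ref_fit) ** 2).sum(axis=-1)
    if weights is None:
        rmsd = float(np.sqrt(diff2.mean()))
    else:
        rmsd = float(np.sqrt((weights * diff2).sum() / weights.sum()))
    return SuperpositionResult(rotation=rot, translation=translation,
                               rmsd_after_fit=rmsd)


def superpose_frames(frames: np.ndarray, reference: np.ndarray,
                     weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Superpose every frame of ``(F, N, 3)`` onto ``reference (N, 3)``."""
    frames = np.asarray(frames, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    _check_fit_coords(reference)
    ref_centroid = _weighted_mean(reference, weights)[0]
    ref_c = reference - ref_centroid
    centroids = _weighted_mean(frames, weights)
    mob_c = frames - centroids
    rots = _batched_rotations(mob_c, ref_c, weights)     # (F, 3, 3)
    return mob_c @ np.swapaxes(rots, -2, -1) + ref_centroid


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                fit_selection: AtomSelection,
                measure_selection: AtomSelection,
                mass_weighted: bool = False) -> np.ndarray:
    """Per-frame RMSD of the measure selection after fitting each frame.

    Each frame is optimally superposed on ``fit_selection`` against the
    reference; the RMSD is then evaluated over ``measure_selection``.
    """
    if len(measure_selection) == 0:
        raise MDCompareError("measure selection is empty")
    if len(fit_selection) < 3:
        raise SuperpositionError("fit selection needs at least 3 atoms")
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != (traj.n_atoms, 3):
        raise MDCompareError("reference must match trajectory atom count")
    fit_idx = fit_selection.as_array()
    meas_idx = measure_selection.as_array()
    weights = traj.topology.masses[fit_idx] if mass_weighted else None

    ref_fit = reference[fit_idx]
    _check_fit_coords(ref_fit)
    ref_centroid = _weighted_mean(ref_fit, weights)[0]
    frames_fit = traj.coords[:, fit_idx]
    centroids = _weighted_mean(frames_fit, weights)
    rots = _batched_rotations(frames_fit - centroids,
                              ref_fit - ref_centroid, weights)
    # apply each frame's fit transform to the measure atoms
    meas = traj.coords[:, meas_idx] - centroids
    fitted = meas @ np.swapaxes(rots, -2, -1) + ref_centroid
    diff2 = ((fitted - reference[meas_idx]) ** 2).sum(axis=-1)   # (F, M)
    if mass_weighted:
        w = traj.topology.masses[meas_idx]
        return np.sqrt((diff2 * w).sum(axis=1) / w.sum())
    return np.sqrt(diff2.mean(axis=1))


def time_averaged_rmsd(traj: Trajectory, reference: np.ndarray,
                       fit_selection: AtomSelection,
                       measure_selection: AtomSelection,
                       mass_weighted: bool = False) -> float:
    """Mean over frames of the per-frame superposed RMSD (Angstrom)."""
    return float(rmsd_series(traj, reference, fit_selection,
                             measure_selection, mass_weighted).mean())


def write_rmsd_tsv(series: np.ndarray, path: str | PathLike,
                   fit_expression: str = "", measure_expression: str = "") -> None:
    """Per-frame RMSD TSV with a trailing time-average summary row."""
    with open(path, "w") as out:
        out.write(f"# fit_selection\t{fit_expression}\n")
        out.write(f"# measure_selection\t{measure_expression}\n")
        out.write("frame\trmsd_A\n")
        for i, value in enumerate(series):
            out.write(f"{i}\t{value:.6f}\n")
        out.write(f"time_average\t{float(np.mean(series)):.6f}\n")
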