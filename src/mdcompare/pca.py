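"""Cartesian-covariance principal component analysis of a trajectory.

The essential-dynamics recipe: remove rigid-body motion by iteratively
superposing all frames on their mean structure, build the 3N x 3N
covariance matrix of the centered Cartesian coordinates, and diagonalize
it.  The leading eigenvectors are the dominant collective motions (PC1
first); projecting the centered coordinates on them gives per-frame
amplitude time series whose normalized histograms summarize each system's
conformational distribution and allow a direct mutant-vs-wild-type shape
comparison.

Numerical conventions: the covariance uses ``1/(F-1)``; eigenvector signs
are fixed so each vector's largest-magnitude element is positive
(reproducible run to run); the eigendecomposition is done on the 3N x 3N
matrix when 3N <= 3000 and on the frames x frames dual Gram matrix
otherwise (identical spectra).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import AtomSelection, Trajectory
from .errors import ComparabilityError, ConvergenceError, MDCompareError
from .rmsd import superpose_frames

__all__ = [
    "PCAResult",
    "PCHistogram",
    "iterative_mean_structure",
    "pca",
    "pc_histogram",
    "compare_pc1",
]

_DUAL_THRESHOLD = 3000  # switch to the frames x frames eigenproblem above this 3N


@dataclass
class PCAResult:
    """Eigen-decomposition of the coordinate covariance of a selection.

    ``eigenvalues`` (A^2) holds the full spectrum, descending;
    ``eigenvectors`` the first k columns (3N each, orthonormal);
    ``projections`` the frames x k amplitude series (A), mean zero by
    construction; ``mean_structure`` the converged iterative mean of the
    selection's coordinates.
    """

    mean_structure: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    selection: AtomSelection

    @property
    def total_variance(self) -> float:
        """Sum of all eigenvalues = trace of the covariance matrix (A^2)."""
        return float(self.eigenvalues.sum())


@dataclass
class PCHistogram:
    """Density-normalized histogram of one projection column."""

    bin_edges: np.ndarray
    density: np.ndarray
    eigenvalue: float


def iterative_mean_structure(traj: Trajectory, selection: AtomSelection,
                             tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Fixed point of superpose-all-frames-then-average.

    Starting from frame 0, all frames are superposed on the current mean
    and re-averaged until the mean moves less than ``tol`` (RMSD, A).
    Raises :class:`ConvergenceError` after ``max_iter`` iterations.
    """
    if traj.n_frames < 2:
        return traj.coords[0, selection.as_array()].copy()
    idx = selection.as_array()
    frames = traj.coords[:, idx]
    mean = frames[0].copy()
    delta = np.inf
    for _ in range(max_iter):
        fitted = superpose_frames(frames, mean)
        new_mean = fitted.mean(axis=0)
        delta = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if delta < tol:
            return mean
    raise ConvergenceError(
        f"mean structure did not converge in {max_iter} iterations "
        f"(last delta {delta:.3e} A)")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude element positive."""
    arg = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[arg, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pca(traj: Trajectory, selection: AtomSelection, k: int = 3) -> PCAResult:
    """Principal component analysis of the selection's Cartesian coordinates.

    Frames are superposed on the iterative mean structure (rigid-body
    motion removed), the 3N-dimensional covariance is diagonalized, and the
    top-``k`` eigenpairs plus projections are returned.  Requires
    ``1 <= k <= min(3N, F-1)``.
    """
    n_frames = traj.n_frames
    if n_frames < 2:
        raise MDCompareError("PCA requires more than one frame")
    idx = selection.as_array()
    if len(idx) == 0:
        raise MDCompareError("PCA selection is empty")
    dof = 3 * len(idx)
    if not (1 <= k <= min(dof, n_frames - 1)):
        raise MDCompareError(
            f"k={k} out of range [1, min(3N={dof}, frames-1={n_frames - 1})]")

    mean = iterative_mean_structure(traj, selection)
    fitted = superpose_frames(traj.coords[:, idx], mean)
    x = (fitted - fitted.mean(axis=0)).reshape(n_frames, dof)

    if dof <= _DUAL_THRESHOLD:
        cov = (x.T @ x) / (n_frames - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
    else:
        gram = (x @ x.T) / (n_frames - 1)
        gvals, gvecs = np.linalg.eigh(gram)
        order = np.argsort(gvals)[::-1]
        gvals = np.clip(gvals[order], 0.0, None)
        gvecs = gvecs[:, order]
        nz = gvals > 1e-12 * max(gvals[0], 1.0)
        evecs = x.T @ gvecs[:, nz]
        evecs /= np.linalg.norm(evecs, axis=0)
        # the dual spectrum only carries F-1 nonzero modes; the remaining
        # eigenvalues of the full covariance are exactly zero
        evals = np.concatenate([gvals, np.zeros(max(dof - len(gvals), 0))])

    top = _fix_signs(evecs[:, :k])
    projections = x @ top
    return PCAResult(mean_structure=mean, eigenvalues=evals,
                     eigenvectors=top, projections=projections,
                     selection=selection)


def pc_histogram(result: PCAResult, component: int = 0,
                 bins: int = 100) -> PCHistogram:
    """Density-normalized histogram of one PC projection.

    The bin range is symmetric about zero and spans the observed extremes,
    so histograms of different systems computed with the same bin count are
    directly comparable after re-binning.
    """
    if bins < 2:
        raise MDCompareError("bins must be >= 2")
    if not (0 <= component < result.projections.shape[1]):
        raise MDCompareError(
            f"component {component} not available (k={result.projections.shape[1]})")
    values = result.projections[:, component]
    half = float(np.max(np.abs(values)))
    if half == 0.0:
        half = 0.5
    edges = np.linspace(-half, half, bins + 1)
    density, edges = np.histogram(values, bins=edges, density=True)
    return PCHistogram(bin_edges=edges, density=density,
                       eigenvalue=float(result.eigenvalues[component]))


def compare_pc1(a: PCAResult, b: PCAResult, bins: int = 100) -> float:
    """Histogram-intersection divergence between two PC1 distributions.

    Both projections are binned on a shared symmetric range; the score is
    ``1 - sum(min(density_a, density_b) * bin_width)``: 0 for identical
    distributions, 1 for disjoint support.  Requires equivalent selections
    (same atom count) in both results.
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ComparabilityError(
            "PCA results were computed on selections of different size")
    if bins < 2:
        raise MDCompareError("bins must be >= 2")
    pa = a.projections[:, 0]
    pb = b.projections[:, 0]
    half = float(max(np.max(np.abs(pa)), np.max(np.abs(pb))))
    if half == 0.0:
        half = 0.5
    edges = np.linspace(-half, half, bins + 1)
    da, _ = np.histogram(pa, bins=edges, density=True)
    db, _ = np.histogram(pb, bins=edges, density=True)
    width = edges[1] - edges[0]
    overlap = float(np.minimum(da, db).sum() * width)
    return float(np.clip(1.0 - overlap, 0.0, 1.0))
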