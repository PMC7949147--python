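"""Trajectory PCA: mode recovery, spectra, histograms, comparisons."""

import numpy as np
import pytest
from scipy.stats import norm

from mdcompare import (PCAResult, Trajectory, compare_pc1,
                       iterative_mean_structure, pc_histogram, pca, select)
from mdcompare.core import AtomSelection
from mdcompare.errors import ComparabilityError, MDCompareError
from mdcompare.rmsd import kabsch_superpose
from mdcompare.synthetic import (GeneratorSpec, gen_mode_trajectory,
                                 gen_rigid_trajectory, gen_toy_complex)


def _all_atoms(topology):
    return select(topology, "chain A or chain B")


def _fake_result(projections, n_coords=30):
    projections = np.asarray(projections, dtype=float)
    evec = np.zeros((n_coords, projections.shape[1]))
    evec[0, 0] = 1.0
    return PCAResult(mean_structure=np.zeros((n_coords // 3, 3)),
                     eigenvalues=np.array([projections[:, 0].var(), 0.0]),
                     eigenvectors=evec, projections=projections,
                     selection=AtomSelection((), "synthetic", n_coords // 3))


class TestIterativeMean:
    def test_static_trajectory_returns_frame0(self, toy_complex):
        topology, base = toy_complex
        traj = Trajectory(topology, np.repeat(base[None], 4, axis=0))
        mean = iterative_mean_structure(traj, _all_atoms(topology))
        assert np.allclose(mean, base)

    def test_rigid_transforms_recover_base_shape(self):
        traj = gen_rigid_trajectory(GeneratorSpec(seed=2, n_frames=50))
        _topology, base = gen_toy_complex(GeneratorSpec(seed=2))
        mean = iterative_mean_structure(traj, _all_atoms(traj.topology))
        # equal to the base up to a global rigid transform
        assert kabsch_superpose(mean, base).rmsd_after_fit < 1e-6

    def test_two_cluster_mean_is_midpoint(self, toy_complex, rng):
        from mdcompare.rmsd import superpose_frames

        topology, base = toy_complex
        delta = rng.normal(size=base.shape)
        delta -= delta.mean(axis=0)
        delta /= np.sqrt((delta ** 2).sum())
        x, y = base + 2.0 * delta, base - 2.0 * delta
        frames = np.array([x if i % 2 == 0 else y for i in range(40)])
        mean = iterative_mean_structure(Trajectory(topology, frames),
                                        _all_atoms(topology))
        midpoint = superpose_frames(np.stack([x, y]), mean).mean(axis=0)
        assert np.sqrt(((mean - midpoint) ** 2).sum(axis=1).mean()) < 1e-3
        # and the mean stays close to the true cluster center
        assert kabsch_superpose(mean, base).rmsd_after_fit < 0.05


class TestPca:
    def test_static_trajectory_has_zero_spectrum(self, toy_complex):
        topology, base = toy_complex
        traj = Trajectory(topology, np.repeat(base[None], 5, axis=0))
        result = pca(traj, _all_atoms(topology), k=2)
        assert np.allclose(result.eigenvalues, 0.0, atol=1e-12)

    def test_planted_mode_recovered(self):
        sc = gen_mode_trajectory(GeneratorSpec(seed=12, n_frames=2000))
        result = pca(sc.trajectory, _all_atoms(sc.trajectory.topology), k=3)
        cos = abs(float(np.dot(result.eigenvectors[:, 0], sc.mode)))
        assert cos >= 0.95
        assert result.eigenvalues[0] / result.eigenvalues[1] >= 10.0

    def test_noise_only_has_no_dominant_mode(self):
        spec = GeneratorSpec(seed=12, n_frames=5000, rigid_noise_sigma=0.05,
                             rigid_max_translation=0.0)
        traj = gen_rigid_trajectory(spec)
        result = pca(traj, _all_atoms(traj.topology), k=3)
        assert result.eigenvalues[0] <= 1.2 * result.eigenvalues[2]

    def test_eigenvalue_sum_equals_trace(self):
        sc = gen_mode_trajectory(GeneratorSpec(seed=3, n_frames=300))
        sel = _all_atoms(sc.trajectory.topology)
        result = pca(sc.trajectory, sel, k=2)
        from mdcompare.rmsd import superpose_frames
        fitted = superpose_frames(sc.trajectory.coords[:, sel.as_array()],
                                  result.mean_structure)
        x = (fitted - fitted.mean(axis=0)).reshape(sc.trajectory.n_frames, -1)
        trace = np.trace(x.T @ x) / (sc.trajectory.n_frames - 1)
        assert result.eigenvalues.sum() == pytest.approx(trace, rel=1e-8)

    def test_orthonormal_vectors_and_centered_projections(self):
        sc = gen_mode_trajectory(GeneratorSpec(seed=3, n_frames=300))
        result = pca(sc.trajectory, _all_atoms(sc.trajectory.topology), k=3)
        gram = result.eigenvectors.T @ result.eigenvectors
        assert np.allclose(gram, np.eye(3), atol=1e-8)
        spread = np.abs(result.projections).max()
        assert np.abs(result.projections.mean(axis=0)).max() < 1e-8 * spread

    def test_full_rank_reconstruction(self):
        spec = GeneratorSpec(seed=5, n_frames=200, residues_per_chain=2)
        sc = gen_mode_trajectory(spec)
        sel = _all_atoms(sc.trajectory.topology)
        k = 3 * len(sel)
        result = pca(sc.trajectory, sel, k=k)
        from mdcompare.rmsd import superpose_frames
        fitted = superpose_frames(sc.trajectory.coords[:, sel.as_array()],
                                  result.mean_structure)
        x = (fitted - fitted.mean(axis=0)).reshape(200, -1)
        assert np.abs(result.projections @ result.eigenvectors.T - x).max() < 1e-8

    def test_rigid_invariance_of_spectrum(self):
        sc = gen_mode_trajectory(GeneratorSpec(seed=8, n_frames=400))
        sel = _all_atoms(sc.trajectory.topology)
        a = pca(sc.trajectory, sel, k=2)
        theta = 0.9
        rot = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1.0, 0],
                        [-np.sin(theta), 0, np.cos(theta)]])
        moved = Trajectory(sc.trajectory.topology,
                           sc.trajectory.coords @ rot.T + [1.0, 2.0, 3.0])
        b = pca(moved, sel, k=2)
        assert np.allclose(a.eigenvalues, b.eigenvalues, rtol=1e-6, atol=1e-10)

    def test_sign_convention_is_reproducible(self):
        sc = gen_mode_trajectory(GeneratorSpec(seed=8, n_frames=200))
        sel = _all_atoms(sc.trajectory.topology)
        a = pca(sc.trajectory, sel, k=3)
        b = pca(sc.trajectory, sel, k=3)
        assert np.array_equal(a.eigenvectors, b.eigenvectors)
        for col in range(3):
            arg = np.abs(a.eigenvectors[:, col]).argmax()
            assert a.eigenvectors[arg, col] > 0

    def test_k_out_of_range(self, toy_complex):
        topology, base = toy_complex
        traj = Trajectory(topology, np.repeat(base[None], 5, axis=0))
        with pytest.raises(MDCompareError, match="out of range"):
            pca(traj, _all_atoms(topology), k=10)  # > frames - 1


class TestHistogram:
    def test_degenerate_projections_single_bin(self):
        result = _fake_result(np.zeros((100, 1)))
        hist = pc_histogram(result, 0, bins=11)
        width = hist.bin_edges[1] - hist.bin_edges[0]
        assert (hist.density > 0).sum() == 1
        assert (hist.density * width).sum() == pytest.approx(1.0, abs=1e-9)

    def test_density_integrates_to_one_and_range_symmetric(self, rng):
        result = _fake_result(rng.normal(0, 2.0, (5000, 1)))
        hist = pc_histogram(result, 0, bins=60)
        width = np.diff(hist.bin_edges)
        assert (hist.density * width).sum() == pytest.approx(1.0, abs=1e-9)
        assert hist.bin_edges[0] == pytest.approx(-hist.bin_edges[-1])

    def test_gaussian_histogram_close_to_normal_cdf(self, rng):
        values = rng.normal(0, 3.0, (10_000, 1))
        hist = pc_histogram(_fake_result(values), 0, bins=100)
        width = np.diff(hist.bin_edges)
        empirical_cdf = np.cumsum(hist.density * width)
        fitted_cdf = norm.cdf(hist.bin_edges[1:], loc=values.mean(),
                              scale=values.std())
        assert np.abs(empirical_cdf - fitted_cdf).max() <= 0.05

    def test_bimodal_mixture_produces_two_separated_peaks(self):
        spec = GeneratorSpec(seed=17, n_frames=4000,
                             mode_mixture=((-15.0, 0.7), (5.0, 0.3)),
                             noise_sigma=0.05)
        sc = gen_mode_trajectory(spec)
        result = pca(sc.trajectory, _all_atoms(sc.trajectory.topology), k=1)
        proj = result.projections[:, 0]
        # align the projection sign with the planted amplitudes
        if np.corrcoef(proj, sc.amplitudes)[0, 1] < 0:
            proj = -proj
        from scipy.signal import find_peaks

        hist = np.histogram(proj, bins=100, density=True)[0]
        maxima, _ = find_peaks(hist, distance=5, prominence=0.2 * hist.max())
        assert len(maxima) == 2
        assert maxima[1] - maxima[0] >= 5
        # the dominant peak belongs to the 70%-weight component
        assert hist[maxima[0]] > hist[maxima[1]]

    def test_bins_and_component_validation(self):
        result = _fake_result(np.zeros((10, 1)))
        with pytest.raises(MDCompareError, match="bins"):
            pc_histogram(result, 0, bins=1)
        with pytest.raises(MDCompareError, match="component"):
            pc_histogram(result, 3, bins=10)


class TestComparePc1:
    def test_self_comparison_is_zero(self, rng):
        result = _fake_result(rng.normal(size=(2000, 1)))
        assert compare_pc1(result, result) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_score_one(self):
        a = _fake_result(np.full((500, 1), -10.0) +
                         np.linspace(0, 0.1, 500)[:, None])
        b = _fake_result(np.full((500, 1), 10.0) +
                         np.linspace(0, 0.1, 500)[:, None])
        assert compare_pc1(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_two_gaussians_match_analytic_overlap(self, rng):
        sigma = 1.0
        a = _fake_result(rng.normal(0.0, sigma, (20_000, 1)))
        b = _fake_result(rng.normal(2.0 * sigma, sigma, (20_000, 1)))
        # equal-width normals 2 sigma apart overlap by 2*Phi(-1)
        expected = 1.0 - 2.0 * norm.cdf(-1.0)
        assert compare_pc1(a, b) == pytest.approx(expected, abs=0.05)

    def test_selection_size_mismatch_rejected(self, rng):
        a = _fake_result(rng.normal(size=(100, 1)), n_coords=30)
        b = _fake_result(rng.normal(size=(100, 1)), n_coords=60)
        with pytest.raises(ComparabilityError):
            compare_pc1(a, b)
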