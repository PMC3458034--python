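import shutil
import subprocess

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import ringmodes as rm
from ringmodes.enm import (
    AnmResult,
    DisconnectedNetworkError,
    GnmResult,
    SpringNetwork,
    anm_cross_correlation,
    anm_decompose,
    anm_deformation_frames,
    build_hessian,
    build_kirchhoff,
    gnm_cross_correlation,
    gnm_decompose,
    gnm_msf,
    mode_contributions,
)
from ringmodes.structure_io import write_calpha_pdb

from conftest import make_line_structure


# ---------------------------------------------------------------- Kirchhoff

def test_path_graph_kirchhoff(line3):
    k = build_kirchhoff(line3, cutoff=7.5)
    np.testing.assert_array_equal(k, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])


def test_triangle_spectrum():
    pts = [[0, 0, 0], [5, 0, 0], [2.5, 5 * np.sqrt(3) / 2, 0]]
    s = make_line_structure(pts, chain_size=3)
    res = gnm_decompose(SpringNetwork(s, cutoff=6.0))
    assert res.n_zero_modes == 1
    np.testing.assert_allclose(res.nonzero_eigenvalues, [3.0, 3.0], atol=1e-12)


def test_kirchhoff_rows_sum_to_zero_and_symmetric(c14_structure):
    k = build_kirchhoff(c14_structure, cutoff=10.0)
    np.testing.assert_array_equal(k, k.T)
    np.testing.assert_array_equal(k.sum(axis=1), np.zeros(len(k)))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_kirchhoff_and_hessian_psd_on_random_clouds(seed):
    """Γ and H of arbitrary point clouds are symmetric positive semidefinite."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 15, size=(12, 3))
    k = build_kirchhoff(pts, cutoff=8.0)
    h = build_hessian(pts, cutoff=8.0)
    for mat in (k, h):
        np.testing.assert_allclose(mat, mat.T, atol=0)
        lam = scipy.linalg.eigvalsh(mat)
        assert lam.min() > -1e-9 * max(lam.max(), 1.0)


def test_scaling_coords_and_cutoff_preserves_kirchhoff(small_structure):
    k1 = build_kirchhoff(small_structure, cutoff=10.0)
    k2 = build_kirchhoff(small_structure.coords * 1.7, cutoff=17.0)
    np.testing.assert_array_equal(k1, k2)


def test_disconnected_network_error_names_components(line3):
    with pytest.raises(DisconnectedNetworkError, match="3 connected components"):
        gnm_decompose(SpringNetwork(line3, cutoff=1.0))


# -------------------------------------------------------- GNM decomposition

def test_gnm_zero_mode_count_and_orthonormality(c14_gnm):
    assert c14_gnm.n_zero_modes == 1
    v = c14_gnm.eigenvectors
    np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)


def test_msf_and_crosscorr_match_pseudoinverse_oracle(small_structure, small_gnm):
    """Mode-sum fluctuations/correlations equal the direct Moore-Penrose
    pseudoinverse of the Kirchhoff matrix (independent closed-form route)."""
    k = build_kirchhoff(small_structure, cutoff=10.0)
    pinv = np.linalg.pinv(k, rcond=1e-10)
    all_modes = range(1, small_gnm.n_nonzero_modes + 1)
    msf = gnm_msf(small_gnm, all_modes)
    np.testing.assert_allclose(msf, np.diag(pinv), atol=1e-8)
    corr = gnm_cross_correlation(small_gnm, all_modes)
    d = np.sqrt(np.outer(np.diag(pinv), np.diag(pinv)))
    np.testing.assert_allclose(corr, pinv / d, atol=1e-8)


def test_mode_contributions_closed_forms():
    def fake(eigs):
        n = len(eigs) + 1
        return GnmResult(np.array([0.0] + list(eigs)), np.eye(n), 1)

    np.testing.assert_allclose(
        mode_contributions(fake([2.0, 2.0, 2.0, 2.0]), 4), [0.25] * 4
    )
    np.testing.assert_allclose(mode_contributions(fake([1.0, 3.0]), 2), [0.75, 0.25])
    with pytest.raises(ValueError):
        mode_contributions(fake([1.0]), 0)
    with pytest.raises(ValueError):
        mode_contributions(fake([1.0]), 5)


def test_msf_rejects_zero_mode(small_gnm):
    with pytest.raises(ValueError):
        gnm_msf(small_gnm, [0])
    with pytest.raises(ValueError):
        gnm_msf(small_gnm, [])


def test_single_mode_crosscorr_is_sign_pattern(small_gnm):
    c = gnm_cross_correlation(small_gnm, [3])
    u = small_gnm.mode_vector(3)
    expected = np.sign(np.outer(u, u))
    np.testing.assert_allclose(c, expected, atol=1e-9)


def test_symmetric_ring_has_only_single_and_double_levels(c14_gnm):
    """Cn symmetry forces the spectrum into non- and doubly-degenerate
    levels; paired levels are exact to 1e-9 relative."""
    lam = c14_gnm.nonzero_eigenvalues[:12]
    groups = [[lam[0]]]
    for x in lam[1:]:
        if (x - groups[-1][-1]) / groups[-1][-1] < 1e-9:
            groups[-1].append(x)
        else:
            groups.append([x])
    assert all(len(g) in (1, 2) for g in groups)
    assert any(len(g) == 2 for g in groups)


def test_gnm_spectrum_invariant_under_rigid_motion(small_structure, small_gnm):
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    moved = small_structure.with_coords(small_structure.coords @ rot.T + [5.0, -3.0, 11.0])
    g2 = gnm_decompose(SpringNetwork(moved, 10.0))
    np.testing.assert_array_equal(g2.eigenvalues, small_gnm.eigenvalues)


# -------------------------------------------------------------------- ANM

def test_dumbbell_hessian_single_stretch_mode():
    pts = make_line_structure([[0, 0, 0], [3.8, 0, 0]], chain_size=2)
    h = build_hessian(pts, cutoff=5.0)
    lam, vec = scipy.linalg.eigh(h)
    assert np.sum(np.abs(lam) < 1e-9 * lam.max()) == 5
    stretch = vec[:, -1].reshape(2, 3)
    # the one nonzero mode is the x-stretch
    assert abs(stretch[:, 0]).min() > 0.7 and np.abs(stretch[:, 1:]).max() < 1e-9


def test_hessian_block_row_sums_vanish(small_structure):
    h = build_hessian(small_structure, cutoff=15.0)
    n = len(small_structure)
    blocks = h.reshape(n, 3, n, 3).sum(axis=2)
    np.testing.assert_allclose(blocks, np.zeros_like(blocks), atol=1e-10)


def test_anm_zero_modes_and_translations(c14_anm):
    assert c14_anm.n_zero_modes == 6
    n = c14_anm.n_nodes
    v = c14_anm.eigenvectors
    np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)
    null = v[:, :6]
    for axis in range(3):
        t = np.zeros(3 * n)
        t[axis::3] = 1 / np.sqrt(n)
        assert np.linalg.norm(t - null @ (null.T @ t)) < 1e-6


def test_anm_eigenvalues_invariant_under_rigid_motion(small_structure):
    a1 = anm_decompose(SpringNetwork(small_structure, 15.0, flavor="ANM"))
    rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
    moved = small_structure.with_coords(small_structure.coords @ rot.T + [1.0, 2.0, 3.0])
    a2 = anm_decompose(SpringNetwork(moved, 15.0, flavor="ANM"))
    scale = a1.eigenvalues[-1]
    assert np.abs(a1.eigenvalues - a2.eigenvalues).max() < 1e-9 * scale


def test_anm_rejects_collinear_input(line3):
    with pytest.raises(ValueError, match="collinear"):
        anm_decompose(SpringNetwork(line3, cutoff=6.0, flavor="ANM"))


def test_anm_slowest_modes_form_degenerate_pairs(c14_anm):
    lam = c14_anm.nonzero_eigenvalues[:4]
    assert (lam[1] - lam[0]) / lam[0] < 1e-9
    assert (lam[3] - lam[2]) / lam[2] < 1e-9
    assert (lam[2] - lam[1]) / lam[1] > 1e-3


def test_anm_crosscorr_bounds_and_diagonal(c14_anm):
    c = anm_cross_correlation(c14_anm, [1])
    assert np.all(c <= 1.0) and np.all(c >= -1.0)
    np.testing.assert_allclose(np.diag(c), 1.0)


# ------------------------------------------------------- deformation frames

def test_deformation_frames_contracts(small_structure):
    anm = anm_decompose(SpringNetwork(small_structure, 15.0, flavor="ANM"))
    frames = anm_deformation_frames(small_structure, anm, mode=1, amplitude=1.5, n_frames=20)
    assert len(frames) == 20
    np.testing.assert_array_equal(frames[0], small_structure.coords)
    max_disp = max(
        np.linalg.norm(f - small_structure.coords, axis=1).max() for f in frames
    )
    assert max_disp == pytest.approx(1.5, abs=1e-6)

    tiny = anm_deformation_frames(small_structure, anm, mode=1, amplitude=1e-9, n_frames=8)
    assert np.abs(tiny[3] - small_structure.coords).max() < 1e-8

    with pytest.raises(ValueError):
        anm_deformation_frames(small_structure, anm, mode=0, amplitude=1.0, n_frames=8)
    with pytest.raises(ValueError):
        anm_deformation_frames(small_structure, anm, mode=1, amplitude=0.0, n_frames=8)


# --------------------------------------------------- external cross-check

def test_gnm_fluctuations_match_bio3d(tmp_path, small_structure, small_gnm):
    """Independent GNM route: the bio3d R package on the same ring and cutoff
    reproduces our mean-square fluctuations up to the global 1/γ scale."""
    assert shutil.which("Rscript"), "Rscript not on PATH"
    pdb = write_calpha_pdb(small_structure, tmp_path / "ring.pdb")
    out = tmp_path / "r_msf.txt"
    script = tmp_path / "gnm.R"
    script.write_text(
        "suppressMessages(library(bio3d))\n"
        f"pdb <- read.pdb('{pdb}')\n"
        "m <- suppressWarnings(gnm(pdb, cutoff=10))\n"
        f"write.table(m$fluctuations, '{out}', row.names=FALSE, col.names=FALSE)\n"
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    r_msf = np.loadtxt(out)
    ours = gnm_msf(small_gnm, range(1, small_gnm.n_nonzero_modes + 1))
    ratio = r_msf / ours
    assert np.ptp(ratio) < 1e-8 * ratio.mean()
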