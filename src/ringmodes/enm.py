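"""Gaussian (GNM) and anisotropic (ANM) elastic network models on Cα nodes.

Nodes are Cα atoms; springs of a single force constant γ connect all node
pairs within a distance cutoff (closed ball, ``d <= r_c``). The GNM works
with the N×N Kirchhoff (connectivity/Laplacian) matrix Γ and yields scalar
per-residue fluctuations and correlations; the ANM works with the 3N×3N
Hessian H and yields directional mode vectors. Both matrices are decomposed
with a full dense symmetric eigensolver — exactness over speed, the rings
considered here stay below a few thousand nodes.

All fluctuation amplitudes are in arbitrary units of 1/γ (k_B T absorbed);
only relative and normalized quantities are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structure_io import CoarseStructure

__all__ = [
    "SpringNetwork",
    "GnmResult",
    "AnmResult",
    "DisconnectedNetworkError",
    "build_kirchhoff",
    "build_hessian",
    "gnm_decompose",
    "anm_decompose",
    "mode_contributions",
    "gnm_msf",
    "gnm_cross_correlation",
    "anm_cross_correlation",
    "anm_deformation_frames",
]

#: relative eigenvalue threshold below which a mode counts as a rigid-body
#: (zero) mode; scale-free.
ZERO_MODE_RTOL = 1e-9


class DisconnectedNetworkError(ValueError):
    """The contact graph at the given cutoff is not connected."""

    def __init__(self, n_components: int, cutoff: float):
        self.n_components = n_components
        super().__init__(
            f"contact network has {n_components} connected components at "
            f"cutoff {cutoff} Å; increase the cutoff"
        )


@dataclass(frozen=True)
class SpringNetwork:
    """A Cα elastic network: structure + cutoff + force constant + flavor."""

    structure: CoarseStructure
    cutoff: float
    spring_constant: float = 1.0
    flavor: Literal["GNM", "ANM"] = "GNM"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.flavor not in ("GNM", "ANM"):
            raise ValueError("flavor must be GNM or ANM")


def _contact_matrix(coords: np.ndarray, cutoff: float) -> np.ndarray:
    d = squareform(pdist(coords))
    adj = (d <= cutoff)
    np.fill_diagonal(adj, False)
    return adj


def _require_connected(adj: np.ndarray, cutoff: float) -> None:
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    if n_comp != 1:
        raise DisconnectedNetworkError(n_comp, cutoff)


def build_kirchhoff(
    structure: CoarseStructure | np.ndarray,
    cutoff: float,
    spring_constant: float = 1.0,
) -> np.ndarray:
    """Kirchhoff (connectivity) matrix Γ: −γ off-diagonal for contacts,
    minus-row-sum diagonal; rows sum to zero exactly."""
    coords = structure.coords if isinstance(structure, CoarseStructure) else np.asarray(structure, float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    adj = _contact_matrix(coords, cutoff)
    if not adj.any():
        raise ValueError(f"all nodes isolated at cutoff {cutoff} Å")
    gamma = spring_constant
    kirchhoff = -gamma * adj.astype(float)
    np.fill_diagonal(kirchhoff, gamma * adj.sum(axis=1))
    return kirchhoff


def build_hessian(
    structure: CoarseStructure | np.ndarray,
    cutoff: float,
    spring_constant: float = 1.0,
) -> np.ndarray:
    """ANM Hessian: 3×3 super-elements −(γ/d²)·r_ij r_ijᵀ for contact pairs,
    diagonal blocks minus the off-diagonal row sums (translation invariance)."""
    coords = structure.coords if isinstance(structure, CoarseStructure) else np.asarray(structure, float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    adj = _contact_matrix(coords, cutoff)
    if not adj.any():
        raise ValueError(f"all nodes isolated at cutoff {cutoff} Å")
    gamma = spring_constant
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(adj, 1))
    for i, j in zip(ii, jj):
        rij = coords[j] - coords[i]
        block = -(gamma / np.dot(rij, rij)) * np.outer(rij, rij)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def _count_zero_modes(eigenvalues: np.ndarray) -> int:
    lam_max = float(eigenvalues[-1])
    return int(np.sum(np.abs(eigenvalues) < ZERO_MODE_RTOL * lam_max))


@dataclass(frozen=True)
class GnmResult:
    """GNM eigendecomposition. Nonzero modes are 1-based, 1 = slowest."""

    eigenvalues: np.ndarray  # full spectrum, ascending
    eigenvectors: np.ndarray  # columns, same order
    n_zero_modes: int

    @property
    def n_nodes(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_nonzero_modes(self) -> int:
        return len(self.eigenvalues) - self.n_zero_modes

    def _check_modes(self, mode_indices: Iterable[int]) -> list[int]:
        modes = sorted(set(int(k) for k in mode_indices))
        if not modes:
            raise ValueError("at least one mode index required")
        for k in modes:
            if not 1 <= k <= self.n_nonzero_modes:
                raise ValueError(
                    f"mode {k} out of range 1..{self.n_nonzero_modes} (zero modes excluded)"
                )
        return modes

    def mode_eigenvalue(self, k: int) -> float:
        """Eigenvalue of nonzero mode k (k = 1 is the slowest)."""
        (k,) = self._check_modes([k])
        return float(self.eigenvalues[self.n_zero_modes + k - 1])

    def mode_vector(self, k: int) -> np.ndarray:
        """Eigenvector (length N) of nonzero mode k."""
        (k,) = self._check_modes([k])
        return self.eigenvectors[:, self.n_zero_modes + k - 1].copy()

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero_modes :].copy()


@dataclass(frozen=True)
class AnmResult:
    """ANM eigendecomposition. Nonzero modes are 1-based, 1 = slowest."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # 3N rows
    n_zero_modes: int

    @property
    def n_nodes(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def n_nonzero_modes(self) -> int:
        return len(self.eigenvalues) - self.n_zero_modes

    _check_modes = GnmResult._check_modes
    mode_eigenvalue = GnmResult.mode_eigenvalue

    def mode_vector(self, k: int) -> np.ndarray:
        """Eigenvector (length 3N) of nonzero mode k."""
        (k,) = self._check_modes([k])
        return self.eigenvectors[:, self.n_zero_modes + k - 1].copy()

    def mode_displacements(self, k: int) -> np.ndarray:
        """Mode k reshaped to per-node 3-vectors, shape (N, 3)."""
        return self.mode_vector(k).reshape(-1, 3)

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero_modes :].copy()


def gnm_decompose(network: SpringNetwork) -> GnmResult:
    """Full symmetric eigendecomposition of the Kirchhoff matrix.

    Requires a connected contact graph (exactly one zero mode); raises
    :class:`DisconnectedNetworkError` naming the component count otherwise.
    """
    coords = network.structure.coords
    adj = _contact_matrix(coords, network.cutoff)
    _require_connected(adj, network.cutoff)
    kirchhoff = build_kirchhoff(network.structure, network.cutoff, network.spring_constant)
    eigenvalues, eigenvectors = scipy.linalg.eigh(kirchhoff)
    n_zero = _count_zero_modes(eigenvalues)
    if n_zero != 1:
        raise RuntimeError(f"expected 1 zero mode for a connected GNM, found {n_zero}")
    return GnmResult(eigenvalues, eigenvectors, n_zero)


def anm_decompose(network: SpringNetwork) -> AnmResult:
    """Full symmetric eigendecomposition of the ANM Hessian.

    Requires a connected, non-collinear structure; verifies that exactly six
    zero modes are present and that the three rigid translations lie in the
    zero-eigenvalue subspace.
    """
    coords = network.structure.coords
    n = len(coords)
    if n < 3:
        raise ValueError("ANM needs at least 3 nodes")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("collinear structure: ANM rotational modes are degenerate")
    adj = _contact_matrix(coords, network.cutoff)
    _require_connected(adj, network.cutoff)
    hessian = build_hessian(network.structure, network.cutoff, network.spring_constant)
    eigenvalues, eigenvectors = scipy.linalg.eigh(hessian)
    n_zero = _count_zero_modes(eigenvalues)
    if n_zero != 6:
        raise RuntimeError(f"expected 6 zero modes for a connected ANM, found {n_zero}")
    # rigid translations must lie in the null space
    null_basis = eigenvectors[:, :n_zero]
    for axis in range(3):
        t = np.zeros(3 * n)
        t[axis::3] = 1.0 / np.sqrt(n)
        residual = t - null_basis @ (null_basis.T @ t)
        if np.linalg.norm(residual) > 1e-6:
            raise RuntimeError("rigid translation not in the ANM null space")
    return AnmResult(eigenvalues, eigenvectors, n_zero)


def mode_contributions(result: GnmResult | AnmResult, n_modes: int) -> np.ndarray:
    """Fractional contribution of the n slowest nonzero modes, ∝ 1/λ,
    normalized to sum to 1 over those n modes."""
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes > result.n_nonzero_modes:
        raise ValueError(f"only {result.n_nonzero_modes} nonzero modes available")
    inv = 1.0 / result.nonzero_eigenvalues[:n_modes]
    return inv / inv.sum()


def gnm_msf(result: GnmResult, mode_indices: Iterable[int]) -> np.ndarray:
    """Per-residue mean-square fluctuation from the selected nonzero modes:
    MSF_i = Σ_k λ_k⁻¹ u_k,i² (arbitrary units of 1/γ)."""
    modes = result._check_modes(mode_indices)
    msf = np.zeros(result.n_nodes)
    for k in modes:
        u = result.mode_vector(k)
        msf += u * u / result.mode_eigenvalue(k)
    return msf


def _normalize_covariance(m: np.ndarray) -> np.ndarray:
    diag = np.diag(m).copy()
    if np.any(diag <= 0) or np.any(diag < 1e-300):
        raise ValueError("zero diagonal in mode covariance: degenerate selection")
    c = m / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def gnm_cross_correlation(result: GnmResult, mode_indices: Iterable[int]) -> np.ndarray:
    """Normalized inter-residue cross-correlation map of the selected modes.

    C_ij = M_ij / sqrt(M_ii M_jj) with M = Σ_k λ_k⁻¹ u_k u_kᵀ. For an exactly
    degenerate pair, M is (up to the common λ) the projector onto the pair's
    eigen-subspace, so the map is invariant to the solver's arbitrary choice
    of basis within the pair.
    """
    modes = result._check_modes(mode_indices)
    cov = np.zeros((result.n_nodes, result.n_nodes))
    for k in modes:
        u = result.mode_vector(k)
        cov += np.outer(u, u) / result.mode_eigenvalue(k)
    return _normalize_covariance(cov)


def anm_cross_correlation(result: AnmResult, mode_indices: Iterable[int]) -> np.ndarray:
    """Normalized N×N cross-correlation from ANM modes:
    T_ij = Σ_k λ_k⁻¹ u_k,i · u_k,j with u_k,i the 3-vector of node i."""
    modes = result._check_modes(mode_indices)
    n = result.n_nodes
    cov = np.zeros((n, n))
    for k in modes:
        disp = result.mode_displacements(k)
        cov += (disp @ disp.T) / result.mode_eigenvalue(k)
    return _normalize_covariance(cov)


def anm_deformation_frames(
    structure: CoarseStructure,
    result: AnmResult,
    mode: int,
    amplitude: float,
    n_frames: int,
) -> list[np.ndarray]:
    """Coordinate frames deforming the structure along one ANM mode.

    Frame t (t = 0..n_frames−1) is R + amplitude·sin(2πt/n_frames)·U, with U
    the mode's per-node displacement field scaled to unit maximum node
    displacement; frame 0 is the input. With n_frames divisible by 4 the
    peak node displacement over the cycle equals ``amplitude`` exactly.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    disp = result.mode_displacements(mode)
    disp = disp / np.linalg.norm(disp, axis=1).max()
    base = structure.coords
    return [
        base + amplitude * np.sin(2 * np.pi * t / n_frames) * disp
        for t in range(n_frames)
    ]
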