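"""Slow-mode structure of Cn rings: degenerate-mode grouping, pair averaging,
hinge detection, GNM↔ANM mode matching and motion-type classification.

Cn symmetry forces the GNM/ANM spectrum of a ring into non-degenerate and
doubly-degenerate levels. Degenerate pairs are grouped by a relative
eigenvalue tolerance and all pair-level quantities (fluctuations,
cross-correlation maps, classification patterns) are computed from the
basis-invariant 2D eigen-subspace, never from individual gauge-dependent
eigenvectors.

The three canonical ring motion types are recognized by template
correlation against the GNM scalar pattern expressed in cylindrical
coordinates (azimuth θ, axial z about the fitted ring axis):

* type I   — ellipsoidal in-plane deformation: pattern ∝ cos(θ − φ),
  degenerate pair;
* type II  — counter-twist of the top (stromal) against the bottom
  (luminal) half: pattern antisymmetric in z, non-degenerate;
* type III — bend/stretch about the mid-plane hinges:
  pattern ∝ cos(θ − φ) · sign(z-half), degenerate pair.

Mode *order* is never part of a contract — only the (group → type)
assignment is; the ranking of the three types may differ between rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enm import (
    AnmResult,
    GnmResult,
    SpringNetwork,
    anm_cross_correlation,
    anm_decompose,
    gnm_cross_correlation,
    gnm_decompose,
    gnm_msf,
)
from .geometry import RingFrame, fit_ring_axis
from .structure_io import CoarseStructure

__all__ = [
    "ModeGroup",
    "RingParameterization",
    "group_degenerate_modes",
    "fold_by_symmetry",
    "detect_hinges",
    "map_similarity",
    "match_gnm_anm",
    "build_ring_parameterization",
    "classify_motion_type",
    "analyze_ring_modes",
    "compare_rings",
]


@dataclass(frozen=True)
class ModeGroup:
    """A (possibly degenerate) group of slow GNM modes and its derived profile."""

    gnm_modes: tuple[int, ...]
    eigenvalues: tuple[float, ...]
    averaged_msf: np.ndarray  # per-residue, arithmetic mean over the group
    averaged_crosscorr: np.ndarray  # N×N, subspace (basis-invariant) map
    matched_anm_modes: tuple[int, ...] = ()
    motion_type: str = "other"  # "I" | "II" | "III" | "other"
    hinge_ranges: tuple[tuple[int, int], ...] = ()
    template_scores: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RingParameterization:
    """Cylindrical frame labels for every residue of a ring."""

    theta: np.ndarray  # azimuth about the axis, [0, 2π)
    z: np.ndarray  # axial coordinate, origin at the Cα centroid, Å
    monomer_index: np.ndarray  # 0-based
    stromal: np.ndarray  # bool: z above the hinge plane (loop side)
    hinge_plane_z: float


def group_degenerate_modes(
    eigenvalues: Sequence[float], n_consider: int, rel_tol: float
) -> list[list[int]]:
    """Group the slowest ``n_consider`` nonzero modes into (near-)degenerate sets.

    Consecutive modes k, k+1 join one group iff (λ_{k+1} − λ_k)/λ_k ≤ rel_tol.
    Cn symmetry allows at most double degeneracy, so runs longer than 2 are
    split at their largest internal relative gap. Returns 1-based mode-index
    groups in ascending eigenvalue order.
    """
    if n_consider < 1:
        raise ValueError("n_consider must be >= 1")
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    lam = np.asarray(eigenvalues, dtype=float)[:n_consider]
    if np.any(lam <= 0):
        raise ValueError("expected strictly positive (nonzero-mode) eigenvalues")

    runs: list[list[int]] = [[1]]
    for k in range(2, len(lam) + 1):
        if (lam[k - 1] - lam[k - 2]) / lam[k - 2] <= rel_tol:
            runs[-1].append(k)
        else:
            runs.append([k])

    def split(run: list[int]) -> list[list[int]]:
        if len(run) <= 2:
            return [run]
        gaps = [
            (lam[run[i + 1] - 1] - lam[run[i] - 1]) / lam[run[i] - 1]
            for i in range(len(run) - 1)
        ]
        cut = int(np.argmax(gaps)) + 1
        return split(run[:cut]) + split(run[cut:])

    return [g for run in runs for g in split(run)]


def fold_by_symmetry(values: np.ndarray, structure: CoarseStructure) -> np.ndarray:
    """Average a per-residue profile over the ring's monomers.

    Returns the monomer-local profile (length = residues per monomer).
    Requires all chains to have equal length.
    """
    if not structure.has_equal_monomers():
        raise ValueError("fold_by_symmetry requires equal monomer lengths")
    n_chains = len(structure.chain_ids)
    values = np.asarray(values, dtype=float)
    if len(values) != len(structure):
        raise ValueError("profile length must match residue count")
    return values.reshape(n_chains, -1).mean(axis=0)


def detect_hinges(
    folded_msf: np.ndarray,
    quantile: float = 0.2,
    min_run: int = 3,
) -> list[tuple[int, int]]:
    """Hinge intervals: maximal runs of low-mobility positions.

    Positions (1-based, monomer-local) whose folded MSF is at or below the
    given profile quantile are merged into runs, tolerating single-position
    gaps; runs shorter than ``min_run`` are dropped. A flat profile has no
    minima and yields no hinges.
    """
    prof = np.asarray(folded_msf, dtype=float)
    if len(prof) < 5:
        raise ValueError("profile too short for hinge detection")
    if np.ptp(prof) < 1e-12 * max(1.0, abs(prof).max()):
        return []
    thresh = np.quantile(prof, quantile)
    low = np.flatnonzero(prof <= thresh) + 1  # 1-based

    intervals: list[list[int]] = []
    for p in low:
        if intervals and p - intervals[-1][1] <= 2:  # allow one-position gap
            intervals[-1][1] = int(p)
        else:
            intervals.append([int(p), int(p)])
    return [(a, b) for a, b in intervals if b - a + 1 >= min_run]


def map_similarity(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation of two square maps over the strict upper triangle."""
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.corrcoef(a[iu], b[iu])[0, 1])


def match_gnm_anm(
    gnm_group_map: np.ndarray,
    anm: AnmResult,
    candidate_modes: Iterable[int],
    slack: float = 0.05,
) -> tuple[tuple[int, ...], dict[int, float]]:
    """Associate ANM modes to a GNM mode group via cross-correlation maps.

    Each candidate ANM mode's single-mode correlation map is compared with
    the group's GNM map by Pearson correlation over the strict upper
    triangle; all candidates within ``slack`` of the best similarity are
    returned (ANM classes of a ring motion are often multi-mode). Also
    returns the per-candidate similarity scores.
    """
    candidates = sorted(set(int(k) for k in candidate_modes))
    if not candidates:
        raise ValueError("candidate mode set is empty")
    sims = {
        k: map_similarity(gnm_group_map, anm_cross_correlation(anm, [k]))
        for k in candidates
    }
    best = max(sims.values())
    matched = tuple(k for k in candidates if sims[k] >= best - slack)
    return matched, sims


def build_ring_parameterization(
    structure: CoarseStructure,
    frame: RingFrame,
    hinge_plane_z: float | None = None,
    folded_msf: np.ndarray | None = None,
) -> RingParameterization:
    """Cylindrical coordinates and half-labels for every residue.

    The stromal/luminal split plane defaults to the axial position of the
    global minimum of a folded MSF profile (the dynamic waist); if neither a
    plane nor a profile is given, the mid-plane z = 0 is used.
    """
    coords = structure.coords - np.asarray(frame.origin)
    axis = np.asarray(frame.axis, dtype=float)
    z = coords @ axis
    # deterministic in-plane reference
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    theta = np.mod(np.arctan2(coords @ e2, coords @ e1), 2 * np.pi)
    theta[theta >= 2 * np.pi] = 0.0  # guard the float edge of np.mod

    if hinge_plane_z is None:
        if folded_msf is not None:
            m = len(folded_msf)
            pos_min = int(np.argmin(folded_msf))
            z_by_pos = z.reshape(-1, m)
            hinge_plane_z = float(z_by_pos[:, pos_min].mean())
        else:
            hinge_plane_z = 0.0
    return RingParameterization(
        theta=theta,
        z=z,
        monomer_index=structure.monomer_index,
        stromal=z >= hinge_plane_z,
        hinge_plane_z=float(hinge_plane_z),
    )


def _pattern_basis(gnm: GnmResult, modes: Sequence[int]) -> np.ndarray:
    """Orthonormal basis of the centered eigen-subspace of a mode group."""
    vecs = np.column_stack([gnm.mode_vector(k) for k in modes])
    vecs = vecs - vecs.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(vecs)
    keep = np.abs(np.diag(r)) > 1e-12
    return q[:, keep]


def _subspace_score(basis: np.ndarray, templates: np.ndarray) -> float:
    """Max |Pearson correlation| between any template row and any unit vector
    in the centered subspace spanned by ``basis``."""
    t = templates - templates.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(t, axis=1)
    ok = norms > 1e-12
    if not ok.any():
        return 0.0
    t = t[ok] / norms[ok, None]
    proj = t @ basis  # (n_templates, dim)
    return float(np.sqrt((proj**2).sum(axis=1)).max())


def classify_motion_type(
    group: ModeGroup | Sequence[int],
    frame_param: RingParameterization,
    gnm: GnmResult,
    corr_threshold: float = 0.6,
) -> tuple[str, dict[str, float]]:
    """Label a slow-mode group as ring motion type I, II, III or "other".

    Template fields on the residues (θ = azimuth, s = ±1 for stromal/luminal
    half) are correlated with the group's GNM eigenvector pattern — for
    degenerate pairs, with the best-matching unit vector of the pair's
    centered 2D eigen-subspace, which is gauge-invariant:

    * I:   cos(θ − φ), phase φ swept on a 1° grid (requires a pair),
    * II:  s(z) (requires a singleton),
    * III: cos(θ − φ)·s(z), φ swept (requires a pair).

    The best size-compatible template wins if its score reaches
    ``corr_threshold``; otherwise "other". Returns (label, scores).
    """
    modes = tuple(group.gnm_modes) if isinstance(group, ModeGroup) else tuple(group)
    basis = _pattern_basis(gnm, modes)
    theta = frame_param.theta
    sign = np.where(frame_param.stromal, 1.0, -1.0)

    phases = np.deg2rad(np.arange(0.0, 180.0, 1.0))  # cos(θ−φ−π) = −cos(θ−φ)
    cos_templates = np.cos(theta[None, :] - phases[:, None])
    scores = {
        "I": _subspace_score(basis, cos_templates),
        "II": _subspace_score(basis, sign[None, :]),
        "III": _subspace_score(basis, cos_templates * sign[None, :]),
    }
    size_ok = {"I": len(modes) == 2, "II": len(modes) == 1, "III": len(modes) == 2}
    candidates = [t for t in scores if size_ok[t]]
    if not candidates:
        return "other", scores
    best = max(candidates, key=lambda t: scores[t])
    label = best if scores[best] >= corr_threshold else "other"
    return label, scores


def analyze_ring_modes(
    structure: CoarseStructure,
    gnm_cutoff: float = 10.0,
    anm_cutoff: float = 15.0,
    n_consider: int = 5,
    degeneracy_tol: float = 0.02,
    hinge_quantile: float = 0.2,
    hinge_min_run: int = 3,
    corr_threshold: float = 0.6,
    match_anm: bool = True,
    anm_candidates: int = 9,
    gnm: GnmResult | None = None,
    anm: AnmResult | None = None,
) -> tuple[list[ModeGroup], RingParameterization, GnmResult, AnmResult | None]:
    """Full slow-mode analysis of one ring.

    Decomposes the GNM (and optionally the ANM), groups the ``n_consider``
    slowest GNM modes into degenerate sets, averages each group's MSF and
    cross-correlation, detects hinge intervals per group, fits the ring
    frame, classifies each group's motion type, and associates ANM modes by
    cross-correlation-map similarity. Precomputed decompositions may be
    passed in to avoid repeating the eigensolves.
    """
    if gnm is None:
        gnm = gnm_decompose(SpringNetwork(structure, gnm_cutoff, flavor="GNM"))
    if anm is None and match_anm:
        anm = anm_decompose(SpringNetwork(structure, anm_cutoff, flavor="ANM"))

    groups_idx = group_degenerate_modes(gnm.nonzero_eigenvalues, n_consider, degeneracy_tol)
    frame = fit_ring_axis(structure)

    # hinge plane from the folded MSF over all considered slow modes
    all_modes = [k for g in groups_idx for k in g]
    folded_all = fold_by_symmetry(gnm_msf(gnm, all_modes), structure)
    param = build_ring_parameterization(structure, frame, folded_msf=folded_all)

    positions = structure.monomer_positions()
    groups: list[ModeGroup] = []
    for g in groups_idx:
        msf = gnm_msf(gnm, g) / len(g)
        folded = fold_by_symmetry(msf, structure)
        hinges_pos = detect_hinges(folded, hinge_quantile, hinge_min_run)
        hinges = tuple(
            (int(positions[a - 1]), int(positions[b - 1])) for a, b in hinges_pos
        )
        crosscorr = gnm_cross_correlation(gnm, g)
        label, scores = classify_motion_type(g, param, gnm, corr_threshold)
        matched: tuple[int, ...] = ()
        if match_anm and anm is not None:
            n_cand = min(anm_candidates, anm.n_nonzero_modes)
            matched, _ = match_gnm_anm(crosscorr, anm, range(1, n_cand + 1))
        groups.append(
            ModeGroup(
                gnm_modes=tuple(g),
                eigenvalues=tuple(float(gnm.mode_eigenvalue(k)) for k in g),
                averaged_msf=msf,
                averaged_crosscorr=crosscorr,
                matched_anm_modes=matched,
                motion_type=label,
                hinge_ranges=hinges,
                template_scores=scores,
            )
        )
    return groups, param, gnm, anm


def compare_rings(
    structures: Sequence[CoarseStructure],
    labels: Sequence[str] | None = None,
    **settings,
) -> pd.DataFrame:
    """Run the slow-mode pipeline on several rings and tabulate the results.

    One row per ring, ordered by ring size; per-ring failures are reported
    in the ``error`` column without aborting the batch. ``settings`` are
    forwarded to :func:`analyze_ring_modes`.
    """
    if labels is None:
        labels = [s.source_label or f"ring_{i}" for i, s in enumerate(structures)]
    rows = []
    for label, structure in zip(labels, structures):
        row: dict = {
            "ring": label,
            "n_monomers": structure.n_monomers or len(structure.chain_ids),
            "motion_types": None,
            "gnm_groups": None,
            "anm_modes": None,
            "error": "",
        }
        try:
            groups, _, _, _ = analyze_ring_modes(structure, **settings)
            row["motion_types"] = tuple(g.motion_type for g in groups)
            row["gnm_groups"] = tuple(g.gnm_modes for g in groups)
            row["anm_modes"] = tuple(g.matched_anm_modes for g in groups)
        except Exception as exc:  # error containment per ring
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values("n_monomers", kind="stable").reset_index(drop=True)
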