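"""Scalar geometry of Cn rings: symmetry axis, height, diameters, waist,
helix kink angles, hydropathy profile and named inter-atom distances.

All diameters are Cα-to-axis based (twice the mean radial distance of a
monomer-local position over its n symmetry copies), not molecular-surface
based; this makes every number reproducible from coordinates alone. The
axis sign convention puts the inter-helix loop side (stroma, for a
chloroplast c-ring) at +z, determined from the chain-midpoint centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .structure_io import CoarseStructure

__all__ = [
    "RingFrame",
    "RingGeometryReport",
    "HydropathyProfile",
    "HYDROPATHY_SCALES",
    "fit_ring_axis",
    "ring_dimensions",
    "narrowest_diameter",
    "kink_angle",
    "hydropathy_profile",
    "named_atom_distance",
]

# Kyte-Doolittle hydropathy; positive = hydrophobic, neutral point 0.
_KYTE_DOOLITTLE = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

#: Named per-residue hydropathy tables: {name: (values, neutral_point)}.
#: Further scales (e.g. a transfer-free-energy table) can be registered by
#: assigning ``HYDROPATHY_SCALES["name"] = (values, neutral)``; for
#: free-energy scales where hydrophobic is negative, register the negated
#: values.
HYDROPATHY_SCALES: dict[str, tuple[dict[str, float], float]] = {
    "kyte-doolittle": (_KYTE_DOOLITTLE, 0.0),
}


@dataclass(frozen=True)
class RingFrame:
    """Fitted cylindrical frame of a ring: centroid origin + unit axis."""

    origin: tuple[float, float, float]
    axis: tuple[float, float, float]
    orientation_convention: str = "loop-side (chain midpoint centroid) at +z"
    symmetry_rmsd: float = float("nan")


@dataclass(frozen=True)
class HydropathyProfile:
    """Per-z-bin mean hydropathy of lipid-facing residues + membrane core."""

    bin_centers: np.ndarray
    mean_hydropathy: np.ndarray
    n_residues: np.ndarray
    core_span: float  # Å
    core_z_range: tuple[float, float]
    boundary_positions: tuple[int, int]  # monomer-local positions at core edges


@dataclass(frozen=True)
class RingGeometryReport:
    height: float
    outer_diameter_top: float
    outer_diameter_bottom: float
    inner_diameter_top: float
    inner_diameter_bottom: float
    narrowest_inner_diameter: float = float("nan")
    narrowest_positions: tuple[int, ...] = ()
    kink_angles: dict = field(default_factory=dict)  # helix label -> degrees
    hydrophobic_span: float = float("nan")
    boundary_positions: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "height": self.height,
            "outer_diameter_top": self.outer_diameter_top,
            "outer_diameter_bottom": self.outer_diameter_bottom,
            "inner_diameter_top": self.inner_diameter_top,
            "inner_diameter_bottom": self.inner_diameter_bottom,
            "narrowest_inner_diameter": self.narrowest_inner_diameter,
            "narrowest_positions": list(self.narrowest_positions),
            "kink_angles": dict(self.kink_angles),
            "hydrophobic_span": self.hydrophobic_span,
            "boundary_positions": list(self.boundary_positions),
        }


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _ring_layout(structure: CoarseStructure) -> tuple[int, int]:
    """(n monomers, residues per monomer); requires equal chains."""
    chains = structure.chain_ids
    if not structure.has_equal_monomers():
        raise ValueError("not ring-like: chains have unequal residue counts")
    n = len(chains)
    if n < 3:
        raise ValueError("not ring-like: fewer than 3 monomers detected")
    return n, len(structure) // n


def fit_ring_axis(structure: CoarseStructure) -> RingFrame:
    """Fit the Cn symmetry axis of a ring.

    Each principal (gyration-tensor) direction is scored by the RMSD of the
    coordinate set under a 2π/n rotation about it, minimized over the
    rotation sense and the cyclic monomer correspondence; the direction with
    the smallest residual wins. Raises ``ValueError("not ring-like ...")``
    when no direction scores below 5 Å RMSD. The axis sign is chosen so the
    chain-midpoint centroid (the loop side of a hairpin ring) lies at +z.
    """
    n, m = _ring_layout(structure)
    coords = structure.coords
    origin = coords.mean(axis=0)
    centered = coords - origin
    if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
        raise ValueError("not ring-like: coordinates are collinear")

    gyration = centered.T @ centered / len(centered)
    _, candidate_axes = np.linalg.eigh(gyration)

    best_axis, best_rmsd = None, np.inf
    for idx in range(3):
        axis = candidate_axes[:, idx]
        for sense in (1.0, -1.0):
            rot = _rotation_about(axis, sense * 2 * np.pi / n)
            rotated = centered @ rot.T
            by_monomer = centered.reshape(n, m, 3)
            rotated_by_monomer = rotated.reshape(n, m, 3)
            for shift in range(1, n):
                target = np.roll(by_monomer, -shift, axis=0)
                rmsd = math.sqrt(((rotated_by_monomer - target) ** 2).sum() / len(centered))
                if rmsd < best_rmsd:
                    best_rmsd, best_axis = rmsd, axis.copy()
    if best_axis is None or best_rmsd > 5.0:
        raise ValueError(f"not ring-like: best symmetry RMSD {best_rmsd:.2f} Å > 5 Å")

    mid = m // 2
    mid_centroid = coords.reshape(n, m, 3)[:, mid, :].mean(axis=0) - origin
    if np.dot(mid_centroid, best_axis) < 0:
        best_axis = -best_axis
    return RingFrame(
        origin=tuple(float(x) for x in origin),
        axis=tuple(float(x) for x in best_axis),
        symmetry_rmsd=float(best_rmsd),
    )


def _cylindrical(structure: CoarseStructure, frame: RingFrame) -> tuple[np.ndarray, np.ndarray]:
    """(z, radial distance) per residue in the fitted frame."""
    coords = structure.coords - np.asarray(frame.origin)
    axis = np.asarray(frame.axis)
    z = coords @ axis
    radial = np.linalg.norm(coords - np.outer(z, axis), axis=1)
    return z, radial


def _class_means(values: np.ndarray, n: int, m: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Mean of a per-residue quantity per monomer-local position (NaN if the
    position has no residue selected by ``mask``)."""
    vals = values.reshape(n, m)
    if mask is None:
        return vals.mean(axis=0)
    msk = mask.reshape(n, m)
    counts = msk.sum(axis=0)
    sums = np.where(msk, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def ring_dimensions(
    structure: CoarseStructure,
    frame: RingFrame,
    slab_fraction: float = 0.15,
) -> RingGeometryReport:
    """Height and end diameters of a ring.

    Within the top and bottom axial slabs (``slab_fraction`` of the height
    each), the outer (inner) diameter is twice the largest (smallest)
    per-position mean radial distance, positions being the monomer-local
    symmetry classes.
    """
    if not 0 < slab_fraction < 0.5:
        raise ValueError("slab_fraction must be in (0, 0.5)")
    n, m = _ring_layout(structure)
    z, radial = _cylindrical(structure, frame)
    height = float(z.max() - z.min())
    slab = slab_fraction * height

    report = {}
    for side, mask in (("top", z >= z.max() - slab), ("bottom", z <= z.min() + slab)):
        if not mask.any():
            raise ValueError(f"empty {side} slab")
        means = _class_means(radial, n, m, mask)
        report[f"outer_diameter_{side}"] = 2 * float(np.nanmax(means))
        report[f"inner_diameter_{side}"] = 2 * float(np.nanmin(means))
    return RingGeometryReport(height=height, **report)


def narrowest_diameter(
    structure: CoarseStructure,
    frame: RingFrame,
    position_tolerance: float = 0.25,
) -> tuple[float, tuple[int, ...]]:
    """Narrowest ring diameter and the monomer-local position(s) attaining it.

    Per position, the radial Cα distance is averaged over the n symmetry
    copies; positions whose mean radius is within ``position_tolerance`` Å
    of the minimum are reported (author numbering of the first chain).
    """
    n, m = _ring_layout(structure)
    _, radial = _cylindrical(structure, frame)
    means = _class_means(radial, n, m)
    rmin = float(means.min())
    positions = structure.monomer_positions()
    where = tuple(int(positions[i]) for i in np.flatnonzero(means <= rmin + position_tolerance))
    return 2 * rmin, where


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _helix_axis(points: np.ndarray, window: int = 4) -> np.ndarray:
    """Axis of a helical Cα segment.

    The Cα trace winds around the helix axis with a ~3.6-residue period,
    which tilts a plain principal-axis fit of a short segment by several
    degrees. Averaging the trace over a one-turn window first cancels the
    winding to first order; the principal axis of the smoothed trace is
    returned. Falls back to the raw fit when the segment is too short to
    smooth.
    """
    if len(points) >= window + 1:
        kernel = np.ones(window) / window
        smoothed = np.column_stack(
            [np.convolve(points[:, d], kernel, mode="valid") for d in range(3)]
        )
        return _principal_axis(smoothed)
    return _principal_axis(points)


def kink_angle(
    structure: CoarseStructure,
    helix_range: tuple[int, int],
    kink_position: int,
) -> tuple[np.ndarray, float]:
    """Helix kink angle from a two-segment principal-axis fit.

    For each monomer, a principal axis is fitted to the Cα of the residues
    before and after the kink position (the kink residue itself excluded);
    the kink angle is arccos |cos| between the two axes, in [0°, 90°].
    Returns per-monomer angles and their arithmetic mean, in degrees.
    Requires at least 4 residues on each side.
    """
    start, end = helix_range
    if not start < kink_position < end:
        raise ValueError("kink position must be inside the helix range")
    angles = []
    for chain in structure.chain_ids:
        pre, post = [], []
        for r in structure.residues:
            if r.chain_id != chain or not start <= r.residue_number <= end:
                continue
            if r.residue_number < kink_position:
                pre.append(r.coords)
            elif r.residue_number > kink_position:
                post.append(r.coords)
        if len(pre) < 4 or len(post) < 4:
            raise ValueError(
                f"chain {chain}: need >= 4 residues on each side of the kink "
                f"(got {len(pre)} / {len(post)})"
            )
        a = _helix_axis(np.asarray(pre))
        b = _helix_axis(np.asarray(post))
        cos = abs(float(np.dot(a, b)))
        angles.append(math.degrees(math.acos(min(1.0, cos))))
    arr = np.asarray(angles)
    return arr, float(arr.mean())


def hydropathy_profile(
    structure: CoarseStructure,
    frame: RingFrame,
    scale: str = "kyte-doolittle",
    bin_width: float = 2.0,
) -> HydropathyProfile:
    """Depth profile of lipid-facing hydrophobicity and the membrane core.

    Residues are binned by axial coordinate (``bin_width`` Å). Within each
    bin only lipid-facing residues count — those in the outer half of the
    bin's radial distribution. The hydrophobic core is the longest
    contiguous run of bins whose mean hydropathy exceeds the scale's
    neutral point; its axial extent is the hydrophobic span and the
    monomer-local positions with mean z nearest each core edge are the
    membrane-boundary positions.
    """
    try:
        values, neutral = HYDROPATHY_SCALES[scale]
    except KeyError:
        raise ValueError(
            f"unknown hydropathy scale {scale!r}; available: {sorted(HYDROPATHY_SCALES)}"
        ) from None
    n, m = _ring_layout(structure)
    names = [r.residue_name for r in structure.residues]
    known = np.array([name in values for name in names])
    if known.mean() <= 0.5:
        raise ValueError("more than half of the residue names are unknown to the scale")
    hydro = np.array([values.get(name, np.nan) for name in names])

    z, radial = _cylindrical(structure, frame)
    edges = np.arange(z.min(), z.max() + bin_width, bin_width)
    if len(edges) < 3:
        edges = np.array([z.min(), z.max() + 1e-9])
    idx = np.clip(np.digitize(z, edges) - 1, 0, len(edges) - 2)

    centers, means, counts = [], [], []
    for b in range(len(edges) - 1):
        in_bin = (idx == b) & known
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        if not in_bin.any():
            means.append(np.nan)
            counts.append(0)
            continue
        median_r = np.median(radial[in_bin])
        facing = in_bin & (radial >= median_r)
        means.append(float(hydro[facing].mean()))
        counts.append(int(facing.sum()))
    means_arr = np.asarray(means)

    # bins left empty by the discrete Cα spacing carry no evidence; bridge
    # them by linear interpolation from the neighboring occupied bins
    valid = ~np.isnan(means_arr)
    if valid.sum() == 0:
        raise ValueError("no occupied z-bins")
    idx_all = np.arange(len(means_arr))
    filled = np.interp(idx_all, idx_all[valid], means_arr[valid])

    # longest contiguous run of hydrophobic bins
    hydrophobic = filled > neutral
    best_run, run_start, cur_start = (0, 0), 0, None
    for b, h in enumerate(np.append(hydrophobic, False)):
        if h and cur_start is None:
            cur_start = b
        elif not h and cur_start is not None:
            if b - cur_start > best_run[0]:
                best_run = (b - cur_start, cur_start)
            cur_start = None
    span = best_run[0] * bin_width
    if best_run[0] == 0:
        return HydropathyProfile(
            np.asarray(centers), means_arr, np.asarray(counts), 0.0, (np.nan, np.nan), ()
        )
    lo_z = edges[best_run[1]]
    hi_z = edges[best_run[1] + best_run[0]]

    z_by_pos = _class_means(z, n, m)
    positions = structure.monomer_positions()
    lo_pos = int(positions[np.argmin(np.abs(z_by_pos - lo_z))])
    hi_pos = int(positions[np.argmin(np.abs(z_by_pos - hi_z))])
    return HydropathyProfile(
        bin_centers=np.asarray(centers),
        mean_hydropathy=means_arr,
        n_residues=np.asarray(counts),
        core_span=float(span),
        core_z_range=(float(lo_z), float(hi_z)),
        boundary_positions=(lo_pos, hi_pos),
    )


def _find_atom(model: gemmi.Model, chain: str, resnum: int, atom: str) -> np.ndarray:
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            if res.seqid.num != resnum:
                continue
            for a in res:
                if a.name == atom:
                    return np.array([a.pos.x, a.pos.y, a.pos.z])
    raise ValueError(f"atom not found: {chain}:{resnum}:{atom}")


def named_atom_distance(
    full_atom_source: str | Path,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
    symmetry_min: bool = False,
) -> float:
    """Euclidean distance (Å) between two named atoms of a full-atom PDB file.

    Selectors are (chain, residue number, atom name). With
    ``symmetry_min=True`` and selectors on different chains, the minimum
    over all symmetry-equivalent chain pairs with the same cyclic offset is
    returned — the reporting convention for inter-monomer contacts of a
    ring.
    """
    path = Path(full_atom_source)
    if not path.is_file():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    model = st[0]
    if not symmetry_min or atom_a[0] == atom_b[0]:
        pa = _find_atom(model, *atom_a)
        pb = _find_atom(model, *atom_b)
        return float(np.linalg.norm(pa - pb))

    chains = [ch.name for ch in model]
    off = (chains.index(atom_b[0]) - chains.index(atom_a[0])) % len(chains)
    dists = []
    for i, ca in enumerate(chains):
        cb = chains[(i + off) % len(chains)]
        try:
            pa = _find_atom(model, ca, atom_a[1], atom_a[2])
            pb = _find_atom(model, cb, atom_b[1], atom_b[2])
        except ValueError:
            continue
        dists.append(float(np.linalg.norm(pa - pb)))
    if not dists:
        raise ValueError("no symmetry-equivalent atom pair found")
    return min(dists)
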