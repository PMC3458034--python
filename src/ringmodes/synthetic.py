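"""Parametric generator of idealized Cn hairpin-helix rings.

Each monomer is a hairpin of two kinked ideal α-helices: an inner helix
(TM1) running up from the bottom face, a short top loop, and an outer helix
(TM2) running back down. Monomer 0 is built explicitly and the remaining
``n - 1`` copies are exact rotations of it about the z axis, so a noise-free
ring is Cn-symmetric to machine precision. Helix axes are two straight
segments meeting at a prescribed kink angle, bent radially so the kink
vertex lies inward of the helix ends — producing the mid-membrane waist
characteristic of real c-rings.

Radial anchoring differs between the walls, mirroring how each ring is
characterized: the inner helix is anchored at its waist (``inner_radius``
is the TM1 axis radius at the kink vertex, the narrowest, functionally
defining level of the pore), while the outer helix is anchored at its ends
(``outer_radius`` is the TM2 axis radius at the membrane surfaces, which
sets the ring's outer diameter). With the default radii this packs the two
helix walls against each other along their whole length, as in real
c-rings, so the hairpin moves as a unit in the slow modes. For ring sizes
other than the 14-mer reference, both radii shift by the amount that keeps
the azimuthal monomer spacing at the waist constant (wall thickness is
monomer-intrinsic; circumference grows with subunit count, as observed
across c-ring stoichiometries).

The generator is an idealization: its contract is hairpin topology, exact
Cn symmetry and recoverable geometric ground truth (axis, radii, kink
angles), not sequence or side-chain packing realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import CoarseStructure, ResidueRecord

__all__ = ["RingSpec", "GroundTruth", "build_synthetic_ring", "perturb_structure"]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass(frozen=True)
class RingSpec:
    """Parameters of a synthetic Cn hairpin ring.

    Lengths in residues, distances in Å, angles in degrees. Defaults emulate
    a 14-fold chloroplast-type c-ring: a 38-residue inner helix and a
    30-residue outer helix joined by a 4-residue loop, ideal α-helix
    geometry (1.5 Å rise, 100°/residue, 2.3 Å backbone radius), and
    mid-helix kinks of 31° (TM1) and 20° (TM2). ``inner_radius`` is the TM1
    helix-axis radius at the waist (kink vertex); ``outer_radius`` is the
    TM2 helix-axis radius at its ends, so the measured outer diameter of a
    noise-free ring is 2·(outer_radius + helix_radius). Radii are quoted
    for the ``reference_n``-mer; other ring sizes shift both radii to keep
    the waist monomer spacing constant (see module docstring).
    """

    n_monomers: int = 14
    tm1_length: int = 38
    tm2_length: int = 30
    loop_length: int = 4
    inner_radius: float = 17.5
    outer_radius: float = 30.0
    helix_rise: float = 1.5
    helix_turn: float = 100.0
    helix_radius: float = 2.3
    kink_angle_tm1: float = 31.0
    kink_angle_tm2: float = 20.0
    kink_fraction: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0
    glu_position: int = 0  # optional 1-based position renamed GLU (0 = none)
    reference_n: int = 14  # ring size at which the radii are quoted
    scale_radii_with_n: int = 1  # 1: shift radii to keep monomer spacing constant

    def __post_init__(self) -> None:
        if self.n_monomers < 3:
            raise ValueError("n_monomers must be >= 3")
        if self.n_monomers > len(_CHAIN_IDS):
            raise ValueError(f"n_monomers must be <= {len(_CHAIN_IDS)}")
        for name in ("tm1_length", "tm2_length"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.loop_length < 0:
            raise ValueError("loop_length must be >= 0")
        for name in ("inner_radius", "outer_radius", "helix_rise", "helix_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.kink_fraction < 1:
            raise ValueError("kink_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("kink_angle_tm1", "kink_angle_tm2"):
            if not 0 <= getattr(self, name) < 90:
                raise ValueError(f"{name} must be in [0, 90) degrees")

    @property
    def residues_per_monomer(self) -> int:
        return self.tm1_length + self.loop_length + self.tm2_length

    def to_config(self) -> str:
        """Flat key=value serialization (one field per line)."""
        return "\n".join(f"{k}={v}" for k, v in vars(self).items()) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "RingSpec":
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            caster = int if fields[key] == "int" else float
            kwargs[key] = caster(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Oracle labels for a generated ring (synthetic; for tests and examples)."""

    axis: tuple[float, float, float]
    kink_angles: dict[str, float]  # helix name -> intended kink, degrees
    kink_positions: dict[str, int]  # helix name -> 1-based monomer-local position
    monomer_index: np.ndarray  # (N,) 0-based
    z_half: np.ndarray  # (N,) "stromal" (top, loop side) / "luminal"
    helix_ranges: dict[str, tuple[int, int]]  # 1-based inclusive position ranges


def _segment_tilts(kink_deg: float, fraction: float) -> tuple[float, float]:
    # Tilts (from vertical) of the two axis segments so that both helix ends
    # sit at the same radius while the kink point is displaced inward.
    kappa = math.radians(kink_deg)
    if kappa == 0:
        return 0.0, 0.0
    f = fraction
    a1 = math.atan2((1 - f) * math.sin(kappa), f + (1 - f) * math.cos(kappa))
    return a1, kappa - a1


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-15:
        return np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1 / (1 + c))


def _kinked_helix(
    n_res: int,
    rise: float,
    turn_deg: float,
    helix_radius: float,
    start: np.ndarray,
    dir_a: np.ndarray,
    dir_b: np.ndarray,
    kink_fraction: float,
    radial: np.ndarray,
) -> np.ndarray:
    """Cα positions of an ideal helix wound along a two-segment kinked axis."""
    arc_total = (n_res - 1) * rise
    s_kink = kink_fraction * arc_total
    kink_point = start + dir_a * s_kink

    # Perpendicular frame for segment A, radial-aligned for determinism
    e1 = radial - np.dot(radial, dir_a) * dir_a
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(dir_a, e1)
    rot = _rotation_between(dir_a, dir_b)
    e1b, e2b = rot @ e1, rot @ e2

    pts = np.empty((n_res, 3))
    turn = math.radians(turn_deg)
    for i in range(n_res):
        s = i * rise
        phi = i * turn
        offset = helix_radius * math.cos(phi), helix_radius * math.sin(phi)
        if s <= s_kink:
            axis_pos = start + dir_a * s
            pts[i] = axis_pos + offset[0] * e1 + offset[1] * e2
        else:
            axis_pos = kink_point + dir_b * (s - s_kink)
            pts[i] = axis_pos + offset[0] * e1b + offset[1] * e2b
    return pts


def _effective_radii(spec: RingSpec) -> tuple[float, float]:
    # Constant monomer spacing at the waist across ring sizes: both radii
    # shift by (n - reference_n) * spacing / 2π; wall thickness is fixed.
    if not spec.scale_radii_with_n or spec.n_monomers == spec.reference_n:
        return spec.inner_radius, spec.outer_radius
    delta = (spec.n_monomers - spec.reference_n) * spec.inner_radius / spec.reference_n
    return spec.inner_radius + delta, spec.outer_radius + delta


def _build_monomer(spec: RingSpec) -> np.ndarray:
    """Monomer 0 at azimuth 0 (TM1) / half-spacing (TM2), bottom at z = 0."""
    z = np.array([0.0, 0.0, 1.0])
    inner_r, outer_r = _effective_radii(spec)

    # TM1: rises from the bottom face; the kink vertex (waist) sits at
    # inner_r, the ends flare outward by the kink excursion.
    r1hat = np.array([1.0, 0.0, 0.0])
    a1, b1 = _segment_tilts(spec.kink_angle_tm1, spec.kink_fraction)
    d1a = math.cos(a1) * z - math.sin(a1) * r1hat
    d1b = math.cos(b1) * z + math.sin(b1) * r1hat
    arc1 = (spec.tm1_length - 1) * spec.helix_rise
    excursion1 = spec.kink_fraction * arc1 * math.sin(a1)
    start1 = (inner_r + excursion1) * r1hat
    tm1 = _kinked_helix(
        spec.tm1_length, spec.helix_rise, spec.helix_turn, spec.helix_radius,
        start1, d1a, d1b, spec.kink_fraction, r1hat,
    )
    h1 = spec.kink_fraction * arc1 * math.cos(a1) + (1 - spec.kink_fraction) * arc1 * math.cos(b1)

    # TM2: outer helix, azimuthally offset by half a monomer spacing,
    # descending from the loop level; ends at outer_r, kink vertex inward.
    theta2 = math.pi / spec.n_monomers
    r2hat = np.array([math.cos(theta2), math.sin(theta2), 0.0])
    a2, b2 = _segment_tilts(spec.kink_angle_tm2, spec.kink_fraction)
    d2a = -math.cos(a2) * z - math.sin(a2) * r2hat
    d2b = -math.cos(b2) * z + math.sin(b2) * r2hat
    start2 = outer_r * r2hat + h1 * z
    tm2 = _kinked_helix(
        spec.tm2_length, spec.helix_rise, spec.helix_turn, spec.helix_radius,
        start2, d2a, d2b, spec.kink_fraction, r2hat,
    )

    # Loop: arc from TM1 top to TM2 top, bulging upward so the loop marks
    # the top (stromal) face.
    if spec.loop_length > 0:
        t = np.linspace(0, 1, spec.loop_length + 2)[1:-1]
        loop = np.outer(1 - t, tm1[-1]) + np.outer(t, tm2[0])
        loop[:, 2] += 2.0 * np.sin(math.pi * t)
    else:
        loop = np.empty((0, 3))

    return np.vstack([tm1, loop, tm2])


def build_synthetic_ring(spec: RingSpec) -> tuple[CoarseStructure, GroundTruth]:
    """Generate a Cn hairpin ring and its geometric ground truth.

    Monomer 0 is rotated by multiples of 2π/n about z, so with
    ``noise_sd = 0`` the ring is exactly Cn-symmetric. Optional isotropic
    Gaussian coordinate noise (``noise_sd`` per axis, seeded) is applied
    after replication and models the imperfect symmetry of experimental
    structures.
    """
    monomer = _build_monomer(spec)
    n = spec.n_monomers
    m = spec.residues_per_monomer

    coords = np.empty((n * m, 3))
    for k in range(n):
        ang = 2 * math.pi * k / n
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        coords[k * m : (k + 1) * m] = monomer @ rot.T

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)

    records = []
    for k in range(n):
        chain = _CHAIN_IDS[k]
        for p in range(m):
            name = "GLU" if (p + 1) == spec.glu_position else "ALA"
            x, y, z = coords[k * m + p]
            records.append(
                ResidueRecord(chain, p + 1, "", name, (float(x), float(y), float(z)))
            )
    structure = CoarseStructure(
        residues=tuple(records),
        n_monomers=n,
        residues_per_monomer=m,
        source_label=f"synthetic_c{n}",
    )

    f = spec.kink_fraction
    kink_pos_tm1 = int(round(f * (spec.tm1_length - 1))) + 1
    kink_pos_tm2 = spec.tm1_length + spec.loop_length + int(round(f * (spec.tm2_length - 1))) + 1
    waist_z = monomer[kink_pos_tm1 - 1, 2]
    z_half = np.where(coords[:, 2] >= waist_z, "stromal", "luminal")
    truth = GroundTruth(
        axis=(0.0, 0.0, 1.0),
        kink_angles={"TM1": spec.kink_angle_tm1, "TM2": spec.kink_angle_tm2},
        kink_positions={"TM1": kink_pos_tm1, "TM2": kink_pos_tm2},
        monomer_index=np.repeat(np.arange(n), m),
        z_half=z_half,
        helix_ranges={
            "TM1": (1, spec.tm1_length),
            "TM2": (spec.tm1_length + spec.loop_length + 1, m),
        },
    )
    return structure, truth


def perturb_structure(structure: CoarseStructure, sd: float, seed: int) -> CoarseStructure:
    """Add seeded isotropic Gaussian displacement (sd per axis, Å) to every Cα."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return structure
    rng = np.random.default_rng(seed)
    coords = structure.coords + rng.normal(0.0, sd, size=(len(structure), 3))
    return structure.with_coords(coords)
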