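"""One-call orchestration: configuration, full ring analysis, report assembly.

``run_full_analysis`` executes structure input → GNM/ANM decomposition →
slow-mode grouping/classification → ring geometry, writes all artifacts
(report.json, modes.csv, per-group MSF and cross-correlation CSVs,
geometry.json, optional ANM deformation trajectories) to an output
directory, and returns the in-memory report. Runs are deterministic for a
fixed configuration; the only randomness is the seeded noise of synthetic
inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .enm import mode_contributions
from .geometry import (
    fit_ring_axis,
    hydropathy_profile,
    narrowest_diameter,
    ring_dimensions,
)
from .modes import ModeGroup, analyze_ring_modes
from .structure_io import CoarseStructure, read_calpha_pdb, write_mode_trajectory
from .synthetic import RingSpec, build_synthetic_ring
from .geometry import kink_angle as _kink_angle

logger = logging.getLogger("ringmodes")

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "PipelineError",
    "run_full_analysis",
    "batch_compare",
    "export_matrix",
]


def export_matrix(matrix: np.ndarray, path: str | Path, fmt: str = "dense") -> Path:
    """Write a matrix as plain text: ``dense`` rows or ``long`` (i, j, value)
    CSV with 0-based indices."""
    path = Path(path)
    matrix = np.asarray(matrix)
    if fmt == "dense":
        np.savetxt(path, matrix, delimiter=",", fmt="%.8g")
    elif fmt == "long":
        ii, jj = np.meshgrid(
            np.arange(matrix.shape[0]), np.arange(matrix.shape[1]), indexing="ij"
        )
        pd.DataFrame(
            {"i": ii.ravel(), "j": jj.ravel(), "value": matrix.ravel()}
        ).to_csv(path, index=False)
    else:
        raise ValueError("fmt must be 'dense' or 'long'")
    return path


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {type(cause).__name__}: {cause}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one full ring analysis.

    Exactly one of ``pdb_path`` / ``ring`` selects the input. Ranges/kinks
    for the helix kink-angle measurement are optional (position intervals in
    monomer-local author numbering); for synthetic input they default to the
    generator's ground truth.
    """

    pdb_path: str = ""
    ring: RingSpec | None = None
    gnm_cutoff: float = 10.0
    anm_cutoff: float = 15.0
    n_modes: int = 30  # modes listed in the contribution table
    n_consider: int = 5  # slowest modes scanned for degenerate groups
    degeneracy_tol: float = 0.02
    hinge_quantile: float = 0.2
    corr_threshold: float = 0.6
    hydropathy_scale: str = "kyte-doolittle"
    tm1_range: tuple[int, int] = (0, 0)  # (0, 0) = not requested
    tm1_kink: int = 0
    tm2_range: tuple[int, int] = (0, 0)
    tm2_kink: int = 0
    trajectory_frames: int = 20  # 0 disables trajectory output
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if bool(self.pdb_path) == (self.ring is not None):
            raise ValueError("exactly one of pdb_path / ring must be set")
        if not 0 < self.hinge_quantile < 1:
            raise ValueError("hinge_quantile must be in (0, 1)")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.gnm_cutoff <= 0 or self.anm_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.n_modes < 1 or self.n_consider < 1:
            raise ValueError("n_modes and n_consider must be >= 1")

    # --- flat key=value serialization -------------------------------------
    def to_config_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "ring":
                if v is not None:
                    lines.extend(
                        f"ring.{k}={val}" for k, val in vars(v).items()
                    )
                continue
            if isinstance(v, tuple):
                v = f"{v[0]},{v[1]}"
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "AnalysisConfig":
        kwargs: dict = {}
        ring_kwargs: dict = {}
        ring_fields = RingSpec.__annotations__
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("ring."):
                rkey = key[5:]
                if rkey not in ring_fields:
                    raise ValueError(f"config line {lineno}: unknown ring key {rkey!r}")
                caster = int if ring_fields[rkey] == "int" else float
                ring_kwargs[rkey] = caster(value)
                continue
            if key not in types:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            t = types[key]
            if "tuple" in str(t):
                a, b = value.split(",")
                kwargs[key] = (int(a), int(b))
            elif "int" in str(t):
                kwargs[key] = int(value)
            elif "float" in str(t):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        if ring_kwargs:
            kwargs["ring"] = RingSpec(**ring_kwargs)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_config_text())
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_config_text(Path(path).read_text())


@dataclass(frozen=True)
class AnalysisReport:
    structure_summary: dict
    geometry: dict
    mode_table: list  # dict rows: mode, eigenvalue, contribution, group, type
    groups: list  # ModeGroup objects
    hinges: dict  # group label -> [[start, end], ...]
    manifest: list
    provenance: dict

    def to_jsonable(self) -> dict:
        return {
            "structure": self.structure_summary,
            "geometry": self.geometry,
            "mode_table": self.mode_table,
            "groups": [
                {
                    "gnm_modes": list(g.gnm_modes),
                    "eigenvalues": list(g.eigenvalues),
                    "contribution": sum(
                        row["contribution"]
                        for row in self.mode_table
                        if row["group"] is not None and row["mode"] in g.gnm_modes
                    ),
                    "type": g.motion_type,
                    "anm_modes": list(g.matched_anm_modes),
                    "hinges": [list(h) for h in g.hinge_ranges],
                    "template_scores": {k: round(v, 6) for k, v in g.template_scores.items()},
                }
                for g in self.groups
            ],
            "hinges": self.hinges,
            "manifest": self.manifest,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_jsonable(), indent=indent, sort_keys=True)


def _load_structure(config: AnalysisConfig) -> tuple[CoarseStructure, object | None]:
    if config.ring is not None:
        structure, truth = build_synthetic_ring(config.ring)
        return structure, truth
    return read_calpha_pdb(config.pdb_path), None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_full_analysis(config: AnalysisConfig, output_dir: str | Path | None = None) -> AnalysisReport:
    """Execute the full pipeline for one configuration.

    When ``output_dir`` is given, all artifacts are written there and listed
    in the report manifest. Report content is deterministic for a fixed
    configuration (no timestamps).
    """
    structure, truth = _stage("input")(_load_structure)(config)
    logger.info("loaded %s: %d residues, %d chains", structure.source_label,
                len(structure), len(structure.chain_ids))

    groups: list[ModeGroup]
    groups, param, gnm, anm = _stage("mode_analysis")(analyze_ring_modes)(
        structure,
        gnm_cutoff=config.gnm_cutoff,
        anm_cutoff=config.anm_cutoff,
        n_consider=config.n_consider,
        degeneracy_tol=config.degeneracy_tol,
        hinge_quantile=config.hinge_quantile,
        corr_threshold=config.corr_threshold,
    )

    geometry = _stage("geometry")(_measure_geometry)(structure, truth, config)

    n_modes = min(config.n_modes, gnm.n_nonzero_modes)
    contrib = mode_contributions(gnm, n_modes)
    group_of = {}
    for gi, g in enumerate(groups, start=1):
        for k in g.gnm_modes:
            group_of[k] = gi
    mode_table = [
        {
            "mode": k,
            "eigenvalue": float(gnm.mode_eigenvalue(k)),
            "contribution": float(contrib[k - 1]),
            "group": group_of.get(k),
            "type": groups[group_of[k] - 1].motion_type if k in group_of else None,
        }
        for k in range(1, n_modes + 1)
    ]

    hinges = {
        f"group_{gi}": [list(h) for h in g.hinge_ranges]
        for gi, g in enumerate(groups, start=1)
    }

    manifest: list[str] = []
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(mode_table).to_csv(out / "modes.csv", index=False)
        manifest.append("modes.csv")
        positions = structure.monomer_positions()
        for gi, g in enumerate(groups, start=1):
            from .modes import fold_by_symmetry

            folded = fold_by_symmetry(g.averaged_msf, structure)
            pd.DataFrame({"position": positions, "msf": folded}).to_csv(
                out / f"msf_group{gi}.csv", index=False
            )
            manifest.append(f"msf_group{gi}.csv")
            np.savetxt(out / f"crosscorr_group{gi}.csv", g.averaged_crosscorr,
                       delimiter=",", fmt="%.6f")
            manifest.append(f"crosscorr_group{gi}.csv")
            if config.trajectory_frames > 0 and anm is not None and g.matched_anm_modes:
                k = g.matched_anm_modes[0]
                from .enm import anm_deformation_frames

                if f"trajectory_anm{k}.pdb" not in manifest:
                    frames = anm_deformation_frames(
                        structure, anm, k, amplitude=2.0,
                        n_frames=config.trajectory_frames,
                    )
                    write_mode_trajectory(structure, frames, out / f"trajectory_anm{k}.pdb")
                    manifest.append(f"trajectory_anm{k}.pdb")
        (out / "geometry.json").write_text(json.dumps(geometry, indent=2, sort_keys=True))
        manifest.append("geometry.json")

    config_text = config.to_config_text()
    report = AnalysisReport(
        structure_summary={
            "source": structure.source_label,
            "n_residues": len(structure),
            "n_chains": len(structure.chain_ids),
            "n_monomers": structure.n_monomers,
            "residues_per_monomer": structure.residues_per_monomer,
        },
        geometry=geometry,
        mode_table=mode_table,
        groups=groups,
        hinges=hinges,
        manifest=manifest,
        provenance={
            "tool": "ringmodes",
            "version": _pkg_version,
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        },
    )
    if output_dir is not None:
        (Path(output_dir) / "report.json").write_text(report.to_json())
    return report


def _measure_geometry(structure: CoarseStructure, truth, config: AnalysisConfig) -> dict:
    frame = fit_ring_axis(structure)
    dims = ring_dimensions(structure, frame)
    narrow, narrow_pos = narrowest_diameter(structure, frame)
    geometry = dims.to_dict()
    geometry["narrowest_inner_diameter"] = narrow
    geometry["narrowest_positions"] = list(narrow_pos)
    geometry["axis"] = list(frame.axis)
    geometry["symmetry_rmsd"] = frame.symmetry_rmsd

    kink_requests = {}
    if config.tm1_range != (0, 0) and config.tm1_kink:
        kink_requests["TM1"] = (config.tm1_range, config.tm1_kink)
    if config.tm2_range != (0, 0) and config.tm2_kink:
        kink_requests["TM2"] = (config.tm2_range, config.tm2_kink)
    if not kink_requests and truth is not None:
        kink_requests = {
            name: (truth.helix_ranges[name], truth.kink_positions[name])
            for name in truth.helix_ranges
        }
    kinks = {}
    for name, (rng, kpos) in kink_requests.items():
        _, mean = _kink_angle(structure, rng, kpos)
        kinks[name] = mean
    geometry["kink_angles"] = kinks

    try:
        prof = hydropathy_profile(structure, frame, scale=config.hydropathy_scale)
        geometry["hydrophobic_span"] = prof.core_span
        geometry["boundary_positions"] = list(prof.boundary_positions)
    except ValueError as exc:
        geometry["hydrophobic_span"] = None
        geometry["boundary_positions"] = []
        geometry["hydropathy_note"] = str(exc)
    return geometry


def batch_compare(configs: Sequence[AnalysisConfig]) -> pd.DataFrame:
    """Run the slow-mode pipeline for several configurations.

    Returns one row per ring (ordered by ring size) with the group → motion
    type assignments; per-row failures are contained in the ``error``
    column.
    """
    if not configs:
        raise ValueError("at least one configuration required")
    rows = []
    for config in configs:
        row: dict = {
            "ring": "", "n_monomers": 0, "motion_types": None,
            "gnm_groups": None, "anm_modes": None, "error": "",
        }
        try:
            structure, _ = _load_structure(config)
            row["ring"] = structure.source_label
            row["n_monomers"] = structure.n_monomers or len(structure.chain_ids)
            groups, _, _, _ = analyze_ring_modes(
                structure,
                gnm_cutoff=config.gnm_cutoff,
                anm_cutoff=config.anm_cutoff,
                n_consider=config.n_consider,
                degeneracy_tol=config.degeneracy_tol,
                hinge_quantile=config.hinge_quantile,
                corr_threshold=config.corr_threshold,
            )
            row["motion_types"] = tuple(g.motion_type for g in groups)
            row["gnm_groups"] = tuple(g.gnm_modes for g in groups)
            row["anm_modes"] = tuple(g.matched_anm_modes for g in groups)
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows).sort_values("n_monomers", kind="stable").reset_index(drop=True)
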