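"""Cα coarse-model I/O: read PDB files, write multi-model mode trajectories.

Only the information an elastic network needs is retained: one record per
residue that has a Cα atom, in chain-major order. Heteroatoms, waters and
alternate conformers beyond the first are dropped. Gemmi does the actual
PDB parsing; a light pre-scan reports malformed fixed-column ATOM lines
with their line number, which gemmi silently tolerates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "ResidueRecord",
    "CoarseStructure",
    "PdbParseError",
    "read_calpha_pdb",
    "write_calpha_pdb",
    "write_mode_trajectory",
]


class PdbParseError(ValueError):
    """Raised for unreadable or malformed PDB input."""


@dataclass(frozen=True)
class ResidueRecord:
    """One Cα node: author chain/number/insertion-code identity plus coordinates."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for residue {self.key()}")

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class CoarseStructure:
    """An ordered Cα coarse model plus optional ring-topology metadata.

    ``n_monomers``/``residues_per_monomer`` are 0 when unknown. When set,
    the residue list is expected to consist of ``n_monomers`` chains of
    equal length, chain-major.
    """

    residues: tuple[ResidueRecord, ...]
    n_monomers: int = 0
    residues_per_monomer: int = 0
    source_label: str = ""

    def __post_init__(self) -> None:
        keys = [r.key() for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue number, insertion code)")
        if self.n_monomers < 0 or self.residues_per_monomer < 0:
            raise ValueError("topology counts must be non-negative")
        if self.n_monomers > 0:
            if self.residues_per_monomer <= 0:
                raise ValueError("residues_per_monomer required with n_monomers")
            if len(self.residues) != self.n_monomers * self.residues_per_monomer:
                raise ValueError(
                    f"{len(self.residues)} residues incompatible with "
                    f"{self.n_monomers} x {self.residues_per_monomer} topology"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of Cα coordinates in Å."""
        return np.array([r.coords for r in self.residues], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain IDs in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    @property
    def monomer_index(self) -> np.ndarray:
        """Per-residue 0-based monomer (chain) index."""
        order = {c: i for i, c in enumerate(self.chain_ids)}
        return np.array([order[r.chain_id] for r in self.residues], dtype=int)

    def monomer_positions(self) -> np.ndarray:
        """Monomer-local author residue numbers, taken from the first chain."""
        first = self.chain_ids[0]
        return np.array(
            [r.residue_number for r in self.residues if r.chain_id == first], dtype=int
        )

    def has_equal_monomers(self) -> bool:
        counts = {}
        for r in self.residues:
            counts[r.chain_id] = counts.get(r.chain_id, 0) + 1
        return len(set(counts.values())) == 1

    def with_coords(self, coords: np.ndarray, source_label: str | None = None) -> "CoarseStructure":
        """Return a copy with replaced coordinates (same residue identities)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.residues), 3):
            raise ValueError(f"expected coords of shape ({len(self.residues)}, 3)")
        residues = tuple(
            replace(r, coords=(float(x), float(y), float(z)))
            for r, (x, y, z) in zip(self.residues, coords)
        )
        return replace(
            self,
            residues=residues,
            source_label=self.source_label if source_label is None else source_label,
        )


def _prescan_pdb(path: Path) -> None:
    # gemmi forgives short/corrupt ATOM lines; report them with line numbers
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            stripped = line.rstrip("\n")
            if len(stripped) < 54:
                raise PdbParseError(f"{path}: line {lineno}: ATOM record shorter than 54 columns")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(stripped[lo:hi])
                except ValueError:
                    raise PdbParseError(
                        f"{path}: line {lineno}: malformed coordinate field "
                        f"{stripped[lo:hi]!r}"
                    ) from None


def read_calpha_pdb(
    path: str | Path,
    model_index: int = 0,
    chains: Iterable[str] | None = None,
) -> CoarseStructure:
    """Read one Cα record per residue from a fixed-column PDB file.

    Parameters
    ----------
    path
        PDB file with at least one ``ATOM`` record carrying a Cα.
    model_index
        0-based index into the MODEL list (0 = first model).
    chains
        Optional set of author chain IDs to keep; default all.

    Only polymer ``ATOM`` records are used (waters/heteroatoms excluded);
    for alternate conformations the first-listed conformer is kept. Residues
    are returned chain-major, sorted by residue number then insertion code.
    ``n_monomers`` is set to the chain count when every chain has the same
    number of Cα residues, else left 0.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if not 0 <= model_index < len(st):
        raise PdbParseError(
            f"{path}: model index {model_index} out of range ({len(st)} models)"
        )
    model = st[model_index]
    wanted = set(chains) if chains is not None else None

    records: list[ResidueRecord] = []
    chain_order: list[str] = []
    for chain in model:
        cid = chain.name
        if wanted is not None and cid not in wanted:
            continue
        per_chain: list[ResidueRecord] = []
        for res in chain:
            if res.het_flag != "A" or res.is_water():
                continue
            ca = None
            for atom in res:
                if atom.name == "CA" and atom.element.name != "Ca":
                    ca = atom  # first-listed altloc wins
                    break
            if ca is None:
                continue
            per_chain.append(
                ResidueRecord(
                    chain_id=cid,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or " ").strip(),
                    residue_name=res.name,
                    coords=(ca.pos.x, ca.pos.y, ca.pos.z),
                )
            )
        if per_chain:
            per_chain.sort(key=lambda r: (r.residue_number, r.insertion_code))
            if cid in chain_order:
                raise PdbParseError(f"{path}: chain {cid} appears twice in model")
            chain_order.append(cid)
            records.extend(per_chain)

    if not records:
        raise PdbParseError(f"{path}: no Cα atoms in the selected model/chains")

    counts = [sum(1 for r in records if r.chain_id == c) for c in chain_order]
    equal = len(set(counts)) == 1 and len(chain_order) > 0
    return CoarseStructure(
        residues=tuple(records),
        n_monomers=len(chain_order) if equal else 0,
        residues_per_monomer=counts[0] if equal else 0,
        source_label=str(path),
    )


def _atom_line(serial: int, record: ResidueRecord, xyz: Sequence[float]) -> str:
    name = " CA "
    icode = record.insertion_code or " "
    return (
        f"ATOM  {serial % 100000:5d} {name}{'':1s}{record.residue_name:>3s} "
        f"{record.chain_id[:1]:1s}{record.residue_number:4d}{icode:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"{'':10s}{'C':>2s}"
    )


def write_calpha_pdb(structure: CoarseStructure, path: str | Path) -> Path:
    """Write a single-model Cα-only PDB file."""
    return write_mode_trajectory(structure, [structure.coords], path)


def write_mode_trajectory(
    structure: CoarseStructure,
    frames: Sequence[np.ndarray],
    path: str | Path,
) -> Path:
    """Write coordinate frames as a multi-model (MODEL/ENDMDL) Cα-only PDB.

    Each frame must supply one 3-vector per residue. Every model re-reads
    through :func:`read_calpha_pdb` to the written coordinates at PDB
    column precision (3 decimals).
    """
    if len(frames) == 0:
        raise ValueError("at least one frame required")
    n = len(structure)
    arrs = []
    for f_idx, frame in enumerate(frames):
        arr = np.asarray(frame, dtype=float)
        if arr.shape != (n, 3):
            raise ValueError(f"frame {f_idx}: expected shape ({n}, 3), got {arr.shape}")
        arrs.append(arr)

    path = Path(path)
    lines: list[str] = []
    for f_idx, arr in enumerate(arrs, start=1):
        lines.append(f"MODEL     {f_idx:4d}")
        serial = 0
        prev_chain: str | None = None
        for rec, xyz in zip(structure.residues, arr):
            if prev_chain is not None and rec.chain_id != prev_chain:
                lines.append("TER")
            serial += 1
            lines.append(_atom_line(serial, rec, xyz))
            prev_chain = rec.chain_id
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
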