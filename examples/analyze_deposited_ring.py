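"""Full analysis of a deposited c-ring crystal structure.

Usage:
    python examples/analyze_deposited_ring.py path/to/3V3C.pdb

Runs the complete pipeline on a real Cα model — e.g. the pea chloroplast
c14 ring (PDB entry 3V3C) — and prints the slow-mode group structure,
hinge intervals, ring geometry, and (for 3V3C) the proton-binding-site
hydrogen-bond distances.
"""

import sys

import ringmodes as rm

if len(sys.argv) != 2:
    sys.exit(__doc__)
path = sys.argv[1]

structure = rm.read_calpha_pdb(path)
print(f"{path}: {len(structure)} Cα, {len(structure.chain_ids)} chains, "
      f"n_monomers={structure.n_monomers}")

groups, param, gnm, anm = rm.analyze_ring_modes(structure)
for i, g in enumerate(groups, 1):
    print(f"group {i}: GNM {g.gnm_modes}  type {g.motion_type}  "
          f"ANM {g.matched_anm_modes}  hinges {g.hinge_ranges}")

frame = rm.fit_ring_axis(structure)
dims = rm.ring_dimensions(structure, frame)
narrow, positions = rm.narrowest_diameter(structure, frame)
print(f"height {dims.height:.1f} Å, inner diameter "
      f"{min(dims.inner_diameter_top, dims.inner_diameter_bottom):.1f} Å, "
      f"narrowest {narrow:.1f} Å at {positions}")

# chloroplast-ring specific extras (author numbering of 3V3C)
if structure.residues_per_monomer >= 75:
    _, tm1 = rm.kink_angle(structure, (4, 41), 23)
    _, tm2 = rm.kink_angle(structure, (46, 75), 61)
    print(f"kink angles: TM1 {tm1:.1f}°, TM2 {tm2:.1f}°")
    chain = structure.chain_ids[0]
    for a, b, sym in [
        ((chain, 61, "OE2"), (chain, 28, "NE2"), False),
        ((chain, 61, "OE2"), (chain, 59, "O"), True),
        ((chain, 61, "OE1"), (chain, 66, "OH"), True),
    ]:
        try:
            d = rm.named_atom_distance(path, a, b, symmetry_min=sym)
            print(f"distance {a[1]}:{a[2]} - {b[1]}:{b[2]}  {d:.2f} Å")
        except ValueError as exc:
            print(f"binding-site distance skipped: {exc}")
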