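"""Slow-mode analysis of a synthetic 14-mer c-ring.

Builds the default idealized Cn hairpin ring, decomposes its GNM/ANM
elastic networks, groups the five slowest GNM modes into degenerate sets
and classifies each group's motion type.
"""

import ringmodes as rm

structure, truth = rm.build_synthetic_ring(rm.RingSpec())
print(f"ring: {structure.source_label}, {len(structure)} residues, "
      f"{structure.n_monomers} monomers")

groups, param, gnm, anm = rm.analyze_ring_modes(structure)
contrib = rm.mode_contributions(gnm, 30)

print("\ngroup  GNM modes  eigenvalue  contribution  type  ANM match  hinges")
for i, g in enumerate(groups, 1):
    c = sum(contrib[k - 1] for k in g.gnm_modes)
    print(f"{i:>5}  {str(g.gnm_modes):>9}  {g.eigenvalues[0]:>9.4f}  "
          f"{c:>11.1%}  {g.motion_type:>4}  {str(g.matched_anm_modes):>9}  {g.hinge_ranges}")

print(f"""
Reading the table: the five slowest modes fall into three groups — a
degenerate pair (type I, ellipsoidal in-plane deformation), a singleton
(type II, counter-twist of the top half against the bottom half) and a
second pair (type III, bend/stretch about the mid-membrane hinges).
The hinge intervals of types II/III bracket the helix kink positions
(TM1 kink at {truth.kink_positions['TM1']}, TM2 kink at {truth.kink_positions['TM2']}),
i.e. the ring pivots about its kinked mid-membrane belt.""")
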