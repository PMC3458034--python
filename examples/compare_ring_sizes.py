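"""Universality of the three ring motion types across stoichiometries.

Real rotary-ATPase c-rings contain 8 to 15 subunits depending on the
organism. This sweep generates one ring per size and shows that the three
slowest GNM mode groups carry the same three motion types in every case.
"""

import ringmodes as rm

structures = []
for n in range(8, 16):
    s, _ = rm.build_synthetic_ring(rm.RingSpec(n_monomers=n))
    structures.append(s)

table = rm.compare_rings(structures, match_anm=False)
print(table[["ring", "n_monomers", "motion_types", "gnm_groups"]].to_string(index=False))

print("""
Every ring size shows types I (ellipsoidal pair), II (counter-twist
singleton) and III (bend/stretch pair) among its three slowest groups —
the slow-mode architecture is set by the toroidal topology, not by the
subunit count.""")
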