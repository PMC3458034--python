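# ringmodes

Elastic-network normal-mode analysis and geometry of Cn-symmetric membrane
protein rings — built around the c-ring of the rotary F<sub>o</sub>F<sub>1</sub>
ATP synthase.

The c-ring is a homo-oligomeric ring of 8–15 hairpin-shaped subunits (two
kinked transmembrane helices joined by a short loop) that rotates in the
membrane to translocate protons. Its slow, collective deformations are
central to how it engages the stator and buffers torque, yet they are
invisible to short molecular-dynamics runs. `ringmodes` extracts them with
coarse-grained elastic network models on Cα nodes:

* **GNM** (Gaussian network model): the N×N Kirchhoff matrix
  Γ<sub>ij</sub> = −γ for ‖r<sub>i</sub>−r<sub>j</sub>‖ ≤ r<sub>c</sub>,
  Γ<sub>ii</sub> = −Σ<sub>j≠i</sub>Γ<sub>ij</sub>, gives per-residue
  mean-square fluctuations MSF<sub>i</sub> = Σ<sub>k</sub> λ<sub>k</sub>⁻¹u<sub>k,i</sub>²
  and cross-correlation maps C<sub>ij</sub> = M<sub>ij</sub>/√(M<sub>ii</sub>M<sub>jj</sub>),
  M = Σ<sub>k</sub> λ<sub>k</sub>⁻¹u<sub>k</sub>u<sub>k</sub>ᵀ.
* **ANM** (anisotropic network model): the 3N×3N Hessian with super-elements
  H<sub>ij</sub> = −(γ/d<sub>ij</sub>²)r<sub>ij</sub>r<sub>ij</sub>ᵀ gives
  directional mode vectors and deformation animations.

On top of the decompositions the package implements the ring-specific
analysis: Cn symmetry forces the slow spectrum into non-degenerate and
doubly-degenerate levels, so modes are **grouped by eigenvalue degeneracy**
and all pair quantities are computed from the gauge-invariant 2D
eigen-subspace. Each group is **classified into one of three motion types**
by template correlation in cylindrical coordinates about the fitted
symmetry axis — I: ellipsoidal (cos θ pattern, pair), II: counter-twist of
the two membrane halves (sign(z) pattern, singleton), III: bend/stretch
about the mid-membrane hinges (cos θ · sign(z), pair) — and **hinges** are
detected as folded-MSF minima. A geometry module measures axis, height,
diameters, the narrowest waist, helix kink angles, hydropathy span and
named inter-atom distances.

Everything is testable offline: a parametric generator builds idealized
Cn hairpin rings with exact symmetry and known ground truth (kink angles,
radii, monomer labels).

## Worked example

```
$ python examples/analyze_synthetic_ring.py
ring: synthetic_c14, 1008 residues, 14 monomers

group  GNM modes  eigenvalue  contribution  type  ANM match  hinges
    1     (1, 2)     0.4717        31.0%     I     (3, 4)  ((14, 28),)
    2       (3,)     0.9834         7.4%    II  (1, 2, 3, 4, 5, 6, 7, 8, 9)  ((18, 26), (57, 62))
    3     (4, 5)     1.3372        10.9%   III     (1, 2)  ((18, 26), (57, 62))
```

The five slowest GNM modes of the 14-mer ring fall into a degenerate pair
(type I — the ring squeezes into an ellipse), a singleton (type II — the
stromal half twists against the luminal half) and a second pair (type III —
monomers bend and stretch about the mid-plane). The hinge intervals of
types II/III, (18–26) and (57–62), bracket the generator's helix kink
positions (19 and 57): the ring pivots about its kinked mid-membrane belt,
which in the real protein carries the proton-binding glutamate.
Contributions are 1/λ fractions over the 30 slowest modes; equal values
within a pair are the signature of symmetry-forced degeneracy.

Geometry of the same ring (`examples/ring_geometry_measurements.py`):

```
height                 54.67 Å
outer diameter (top)   64.53 Å (generator: 64.6)
narrowest diameter     32.08 Å at position(s) (21,) (TM1 kink at 19)
TM1 kink angle        31.26°  (generator: 31.0°)
TM2 kink angle        20.74°  (generator: 20.0°)
```

`examples/compare_ring_sizes.py` sweeps rings of 8–15 subunits and finds
the same three motion types in the three slowest groups of every size;
`examples/analyze_deposited_ring.py` runs the identical pipeline on a real
crystal structure.

There is also a thin CLI: `ringmodes analyze | synth | compare | distance`
(see `ringmodes --help`).

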