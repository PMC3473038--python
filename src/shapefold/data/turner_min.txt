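# turner-min: a compact, self-contained nearest-neighbor free-energy set
# (kcal/mol at 37 degrees C) in the style of the Turner rules: helix stacks,
# length-dependent hairpin/bulge/internal initiations with Jacobson-Stockmayer
# long-loop extrapolation, a linear (capped) internal-loop asymmetry penalty
# and an affine multiloop model.  Values are rounded, representative numbers
# chosen for a standalone engine; the set deliberately omits tetraloop bonuses,
# terminal mismatches, 1x1/2x2 special tables, dangles and coaxial stacking.
# Stack entries obey the 180-degree rotational symmetry
#   stack(XY, WZ) = stack(ZW, YX).

[general]
temperature 310.15
theta 3
max_loop 30
js_coeff 1.75

[stack]
# outer-pair inner-pair dG  (outer = (i,j), inner = (i+1,j-1), 5'->3')
AU AU -0.9
AU UA -1.1
AU CG -2.2
AU GC -2.1
AU GU -0.6
AU UG -1.4
UA AU -1.3
UA UA -0.9
UA CG -2.4
UA GC -2.1
UA GU -1.0
UA UG -1.3
CG AU -2.1
CG UA -2.1
CG CG -3.3
CG GC -2.4
CG GU -1.4
CG UG -2.1
GC AU -2.4
GC UA -2.2
GC CG -3.4
GC GC -3.3
GC GU -2.5
GC UG -1.5
GU AU -1.3
GU UA -1.4
GU CG -1.5
GU GC -2.1
GU GU -0.5
GU UG 0.5
UG AU -1.0
UG UA -0.6
UG CG -2.5
UG GC -1.4
UG GU -0.5
UG UG -0.5

[hairpin]
# loop length  initiation
3 5.4
4 5.6
5 5.7
6 5.4
7 6.0
8 5.5
9 6.4

[bulge]
1 3.8
2 2.8
3 3.2
4 3.6
5 4.0
6 4.4

[internal]
# total unpaired (both sides)  initiation
2 1.5
3 1.6
4 1.7
5 2.0
6 2.0

[multiloop]
a 3.4
b 0.4
c 0.0

[asymmetry]
coeff 0.6
max 3.0
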