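# Methods

## Model and algorithm

A secondary structure over an RNA sequence `a_1 … a_n` is a set of
Watson–Crick or GU pairs with no base triples and no pseudoknots; every
hairpin encloses more than θ unpaired bases (θ = 3 by default).  Probing
data enters as a vector `q`, `q_i` = probability that position *i* is
unpaired.  The method tilts the Boltzmann ensemble with per-position weights

    ω(i, x) = exp(−β |x − q_i| / RT),   x = 1 ⇔ unpaired,

so a structure S carries total data weight `exp(−β d(S,q)/RT)` with
`d(S,q) = Σ_i |x_i(S) − q_i|`.  The weighted partition function
`Z' = Σ_S exp(−E(S)/RT) exp(−β d(S,q)/RT)` is computed by the inside
recursion (0-based intervals `[i..j]`, all Boltzmann factors `e^(−E/RT)`,
`Ω(i,j)` the product of unpaired weights over `[i..j]`, empty products = 1):

    Z(i,j)  = Z(i,j−1)·ω(j,1) + Σ_k Z(i,k−1)·ZB(k,j)           (k ≤ j−θ−1)
    ZB(i,j) = ω(i,0)ω(j,0) · [ e^(−E_hairpin(i,j)/RT)·Ω(i+1,j−1)
              + Σ_{i<k<l<j} e^(−E_internal(i,j,k,l)/RT)·Ω(i+1,k−1)·Ω(l+1,j−1)·ZB(k,l)
              + e^(−(a+b)/RT)·Σ_h ZM(i+1,h−1)·ZM1(h,j−1) ]
    ZM1(i,j) = Σ_l ZB(i,l)·e^(−b/RT)·e^(−c(j−l)/RT)·Ω(l+1,j)
    ZM(i,j)  = Σ_k [ e^(−c(k−i)/RT)·Ω(i,k−1) + ZM(i,k−1) ]·ZM1(k,j)

with `Z(i,i−1) = 1` seeding empty intervals.  The defining contract is that
**every position contributes exactly one weight factor per structure**
(paired weight if paired — regardless of partner — unpaired weight
otherwise); pair-specific weights (mutate-and-map style data) are out of
scope.  With all ω = 1 the recursion is exactly McCaskill's classic
partition function.

Pair probabilities come from an outside pass over the same grammar: the
outside value of a candidate pair sums its exterior placement, enclosure in
an internal loop, and multiloop membership (decomposed as last-component
next to a ZM block, or with component blocks on either side, using
inclusion of the ZM/unpaired alternatives minus the no-other-component
case).  `p'_ij = Q_out(i,j)·ZB(i,j)/Z'` and `u'_i = 1 − Σ_j p'_ij`.

The weighted MFE replaces sums by minimizations and products by sums — the
objective becomes `E(S) + β·d(S,q)` with per-position pseudo-energies
`β·q_i` (paired) and `β·(1−q_i)` (unpaired) — followed by a deterministic
traceback (the smallest split index wins ties, so outputs are reproducible;
for the competing-helix degeneracy this resolves toward the
rightmost-closing helix of the F recursion's scan order).

### Diagnostics

* Expected distance, in O(n) from unpaired probabilities:
  `ED = Σ_i [u_i(1−q_i) + (1−u_i)q_i]` (also valid with raw reactivities in
  place of q for the unnormalized variant; missing entries are skipped).
* Critical distance `d* = (RT/β)·ln(Z/Z')`, derived from the sign property
  `P'(S) > P(S) ⇔ exp(−β d/RT)/Z' > 1/Z ⇔ d < (RT/β)ln(Z/Z')`.  Its
  β → 0⁺ limit is the unweighted ED (L'Hôpital on `ln Z'(β)`); the
  implementation returns that limit only when the caller provides it, since
  it is not derivable from the two log-partition values alone.
* Pointwise entropy `H_i = −Σ_j p_ij ln p_ij − u_i ln u_i` (full) or the
  binary form on `(u_i, 1−u_i)`; natural logarithm (nats) throughout so
  averages are comparable run to run.
* Morgan–Higgs diversity `D = 2 Σ_{i<j} p_ij(1−p_ij)`, the expected
  symmetric-difference distance between two independent draws from the
  ensemble — exact by linearity of expectation regardless of correlations.

### Stacking pseudo-energy comparison mode

The alternative (Deigan-style) model adds `ΔG_i = m·ln(1+s_i) + b` for raw
reactivity `s_i` (defaults m = 1.8, b = −0.8 kcal/mol; missing → no term) to
positions in helix stacks only.  Operationally the engine adds the
pseudo-energies of all four positions to every stack term
`E_internal(i,j,i+1,j−1)`, which yields exactly two applications for a pair
flanked by helix neighbors on both sides, one for helix-end pairs, and none
for isolated pairs or loop positions — matching per-structure scoring, as
the tests verify.  All position weights are 1 in this mode.

## Energy model

`turner-min` is a compact, self-contained nearest-neighbor set (kcal/mol,
37 °C): full 6×6 stack table obeying the 180°-rotation symmetry
`stack(XY,WZ) = stack(ZW,YX)`; hairpin initiations for loops 3–9, bulges
1–6, internal loops 2–6, each extrapolated beyond the table by
Jacobson–Stockmayer `E(u_max) + 1.75·RT·ln(u/u_max)`; size-1 bulges keep
the flanking stack energy; internal-loop asymmetry costs 0.6 kcal/mol per
unpaired-length difference, capped at 3.0; multiloops are affine
`a + b·branches + c·unpaired` with a = 3.4, b = 0.4, c = 0.0 (branches count
includes the closing pair); internal/bulge loops above 30 unpaired bases
are forbidden.  R = 0.0019872 kcal/(mol·K); T defaults to 310.15 K and a
temperature override rescales RT only (no enthalpy tables).  Deliberately
omitted, matching the scope of a standalone engine: dangles, coaxial
stacking, terminal mismatches, tetraloop bonuses and 1×1/2×2 special
tables.  Consequently the absolute free energies differ from
RNAstructure/ViennaRNA; correctness is instead established against
exhaustive enumeration *under the same model*, which makes every
equivalence test parameter-set independent.

## Normalization

SHAPE reactivities are mapped piecewise-linearly through configurable knots,
default `(0→0, 0.25→0.35, 0.3→0.55, 0.7→0.85, 2.2→1)` — anchored on the
conventional moderate (0.3) and high (0.7) reactivity thresholds — with
negatives clamped to 0 and values above 2.2 to 1.  These knots are package
defaults, deliberately exposed in `NormalizationConfig` (and as a YAML
config) as the single source of truth.  In-line probing intensities are
quantile-normalized: at/below the 2.5th percentile → 0, at/above the 97.5th
→ 1, linear in between; a constant profile carries no scale and maps to
all 0.5 with a warning.  Both maps are monotone and [0,1]-bounded (property
tested).  Missing values (absent positions or the `.shape` sentinel −999)
stay missing through normalization and are resolved to a fill probability,
default 0.5, which makes the paired and unpaired weights at that position
identical — no information.  With *all* data missing the weighted fold
equals the plain fold up to the constant factor `exp(−β/2RT)^n`.

## Numerical choices

* β carries kcal/mol and divides by RT in the exponent; default 1.0,
  grid-searched in `[0, 3]` (step 0.1) when a reference is available.  The
  grid-search objective is sensitivity + PPV by default (product and min
  are available); ties break toward the smallest β.
* Scaling: by the one-weight-per-position contract, dividing both weights
  of every position by a per-nucleotide scale s multiplies each structure's
  term by `s^−n` uniformly, so probabilities are invariant and
  `log Z' = log(Z'_scaled) + n·ln s`.  For n ≤ 60 s = 1 (small cases stay
  bit-transparent); above that s is set from the weighted MFE
  (`ln s = −1.07·score/(n·RT)`), the standard estimate that keeps the
  tables in range for n up to several thousand at 37 °C; a non-finite
  partition function raises rather than returning garbage.
* Loop-weight products over arbitrary spans use prefix sums of logs
  (exact to ~1e−15 relative), keeping each DP use O(1) without underflow.
* Traceback tolerance 1e−6 kcal/mol for recognizing the minimizing branch;
  equal-scoring alternatives resolve deterministically as above.
* 0/0 accuracy ratios (empty prediction or empty reference) are reported as
  null, never 0 or 1.

## Synthetic data

The generator emulates probing experiments at desk scale: random sequences
(length 8–16) with structures drawn uniformly from the enumerated structure
space; designed multi-stem-loop sequences with a known target; normalized
profiles `q = x ± U(0, noise)` clipped to [0,1], with configurable fractions
of missing positions and of *discordant* positions reporting the opposite
pairing state (emulating the discrepancies real probing data shows against
crystal structures — tertiary contacts, differential reagent reactivity);
raw SHAPE-like profiles place paired positions in `[0, 0.25]` and unpaired
in `[0.7, 2.2]` on the conventional scale.  What this does **not** emulate:
correlated noise along the backbone, sequence-dependent reagent bias,
normalization artifacts of real electropherograms, and tertiary-structure
protections — so passing tests demonstrate algorithmic correctness and the
guaranteed ensemble properties, not benchmark accuracy on real RNAs, which
additionally depends on energy-model completeness (dangles, coaxial
stacking) outside this package's scope.

Default study conditions used by the acceptance script: a two-helix RNA
(stems of 5 bp, loops of 4, 3-nt linkers; n = 34), noise 0.25, 10% missing,
10% discordant, β = 1; engine validation on 60 random instances of length
8–14 with β ∈ {0, 0.5, 1, 2}.  Sizes were chosen so exhaustive enumeration
stays exact and the whole run completes in seconds.

## Known limitations

Single sequences only; no pseudoknots, suboptimal sampling, centroid/MEA
structures, or pair-specific weights; the energy model is intentionally
minimal (see above); CT/dot-bracket parsing accepts non-canonical reference
pairs only outside the folding engine (warn-and-keep by default, reject
inside the engine).  The outside pass is O(n⁴) worst case in its multiloop
term (vectorized; comfortable to a few hundred nucleotides, which covers
the intended use).
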