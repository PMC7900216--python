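# Methods

## The duplex ensemble

The elementary quantity is the hybridization partition function of two
short DNA fragments: an L-strand fragment and an H-strand fragment, both
5′→3′, hybridizing antiparallel and intermolecularly. A *configuration* is
a non-crossing set of base pairs organized into helices, under a grammar
chosen to be the minimal one in which every energy term is well defined:

- a helix is a run of ≥2 stacked pairs (a lone pair has no nearest-neighbor
  stack and is inadmissible);
- each stack is either Watson–Crick/Watson–Crick or a tabulated internal
  single-mismatch context; consequently mismatched pairs never terminate a
  helix and never stack on one another;
- helices are separated by internal loops/bulges of 1..`max_loop` total
  unpaired nucleotides, scored ΔG(s) = a + c·ln s (Jacobson–Stockmayer
  form); larger loops are inadmissible;
- one duplex-initiation term per configuration, a terminal A·T penalty at
  each configuration end; dangling-end terms are omitted;
- N is unpairable; hairpins and pseudoknots are out of scope;
- the empty (unhybridized) state is excluded — hybridization-independent
  deletion formation is modeled separately as the l = 0 mixture component.

Z = Σ exp(−ΔG/RT) over admissible configurations. Z = 0 iff no
configuration exists (e.g. no two stackable WC pairs).

**Parameters.** ΔG°37 values at 1 M NaCl, no salt correction: the unified
Watson–Crick stack set, published internal single-mismatch NN parameters,
duplex initiation 1.937 kcal/mol and terminal A·T penalty 0.06 kcal/mol
(derived from the published ΔH/ΔS tables at T = 310.15 K; a unit test
cross-checks the packaged table against the ΔH/ΔS source shipped with
Biopython). Loop defaults a = 3.2 kcal/mol, c = 1.5 kcal/mol (≈2.44·RT at
37 °C), `max_loop` = 6: DNA internal loops are strongly destabilizing
(Boltzmann factor < 10⁻³ already at s = 2), so the cutoff excludes only
negligible states while bounding the DP cost. All values live in
`src/mtmisalign/thermo/data/unified_37C.tsv` and alternative sets can be
loaded from any file with the same three-column schema. R = 0.0019872
kcal/mol/K. Changing the temperature re-weights the Boltzmann factors but
keeps the ΔG°37 tables (no ΔH/ΔS decomposition — melting-curve prediction
is a non-goal); this preserves the T → 0 (MFE) and T → ∞ (configuration
count) limits used in the tests.

**Evaluation.** Three independent routes compute the same ensemble:
(1) a per-pair log-space DP (`duplex_partition_function`) that cannot
overflow up to the 200-nt input cap and also returns the MFE;
(2) a linear-space numba kernel (`pf_matrix`) evaluating all l×l segment
pairs of two genomic regions — exact in float64 for the ≤100-nt analysis
grid (worst-case exponent ≈ e³⁶⁰ for a perfect GC 100-mer, within float64
range); (3) a brute-force enumerator over all monotone pair chains
(`enumerate_configurations`), mirroring the grammar clause by clause, used
as the oracle for both. DP-vs-oracle agreement is enforced at 10⁻⁹
relative tolerance (observed ≈10⁻¹⁵).

## Windows, propensities, bins

Coordinates are 1-based inclusive on the circular reference (L-strand);
the H-strand is its reverse complement and is represented by
reference-coordinate intervals plus orientation, so one coordinate system
serves both strands. Windows may wrap the origin.

For breakpoint (p5, p3) and half-width W = 100, the propensity of position
pair (i, j) at length l sums Z over the l × l segment pairs whose L-segment
covers p5+i and whose H-segment covers p3+j. Segments overhanging the
window edge are read from the circular genome, not truncated: the window
bounds which position pairs are scored, not which sequence is visible.
Because an L-segment pairs an H-segment exactly where the two *reference*
segments are identical, the hybridization picture coincides with the
direct-repeat picture of misalignment.

Bins tile offsets −W..W−1 with 2W/b bins per axis (b = 10 by default; the
single offset +W is dropped, giving 20 × 20 = 400 bins and the uniform
value 1/400 for l = 0). The breakpoint (offset 0, 0) lies at the left edge
of bin (10, 10). An all-zero window (possible on pathological synthetic
input) falls back to uniform bins with a logged warning so likelihoods
stay finite; individual zero entries at some lengths are legitimate and
are handled by the fit.

**The engine.** `PropensityEngine` clusters breakpoints by proximity
(greedy 1-D splits at `max_span` = 4000 nt per axis), evaluates each
distinct segment-pair partition function once per cluster region and
length, and stores summed-area tables; every map value, bin and profile is
then an O(1) rectangle sum, bit-identical to direct evaluation. This is
the pre-computed-arc strategy that makes n×9-length component matrices
affordable: the full n = 2000 recovery experiment below costs ~2 minutes
on one CPU. `pad` widens regions so bootstrap resamples (shifted within
each window) stay covered.

**A property of the center-bin statistic worth knowing.** For a clean
planted repeat of length l\* spanning the breakpoint, the profile
p_l peaks *at or below* l\*: sub-duplexes at shorter lengths concentrate
the same diagonal signal into fewer bins, so their center-bin share is
larger (measured p₅ = 0.49 vs p₁₀ = 0.26 for a sterile planted 10-mer).
Exact argmax identification holds only for repeats up to about half a bin
(l\* = 5 at the defaults). This is intrinsic to normalizing a multi-bin
signal by bin, not a parameterization artifact; the mixture fit uses the
full profile, not the argmax, and remains informative. In real genomes the
profile is dominated by diffuse context homology — a breakpoint with only
a 5-nt perfect repeat can peak at 20 nt.

## The mixture model and its fit

P[i, l] is deletion i's relative breakpoint-bin propensity at grid length
l (column l = 0 is constant 1/400). The weights θ on the simplex maximize
Σᵢ log Σₗ θₗ P[i, l] — a concave problem solved by EM (responsibilities
r ∝ θₗP, θ ← mean r), uniform start, relative log-likelihood tolerance
10⁻⁹, 10,000 iteration cap; the log-likelihood is non-decreasing by
construction and guarded at every step. A multi-start option (random
Dirichlet starts) exists as a ridge check and must agree with the uniform
start. Flat likelihoods (e.g. identical uniform rows) resolve to the
uniform-start fixed point and set a non-identifiability flag when the
projected Hessian of the log-likelihood is near-singular (smallest
eigenvalue < 10⁻⁸ of the largest). Grouped summaries: short = θ₀+θ₅,
medium = θ₁₀+θ₁₅+θ₂₀+θ₂₅, long = θ₅₀+θ₇₅+θ₁₀₀.

**Bootstrap.** Parametric-within-window: per replicate, each deletion
draws l ~ θ̂ and then a bin within its own window with probability equal
to the relative bin propensity at l; the simulated breakpoint sits at the
bin center, the replicate is refitted, and grouped SDs are the sample SDs
of the grouped weights across B replicates (computed on grouped weights
per replicate, not from per-l SDs). B = 100 by default, fully
seed-reproducible. Whether the original study drew its error-bar datasets
from the fitted mixture or from a null is not documented; the parametric
choice here is an assumption and is flagged as such.

## The synthetic-data generator

`SimulationSpec` defaults describe the validation conditions: a 16-kb
i.i.d. circular genome at GC 0.44 (mammalian-mtDNA-like), n = 2000
deletions, candidate 5′ and 3′ arcs of 400 nt (positions 3000–3400 and
11000–11400) sampled on a 10-nt lattice so that sampling resolution equals
analysis resolution, and θ* = (0.2 @ 0, 0.5 @ 5, 0.3 @ 20). The arc
width is a deliberately scaled stand-in for a full major arc; the engine's
shared tables make these conditions runnable end-to-end in minutes, and
context-diversity experiments (several scattered hotspot arc-pairs) showed
no accuracy benefit that would justify the extra cost. Optional planted
perfect repeats embed known direct-repeat signal at recorded positions.

Three placement modes:

- **model** (default): samples (l, x) jointly ∝ θ*ₗ·f_l(x)·h(x), where
  f_l(x) is the relative breakpoint-bin propensity of candidate pair x —
  the exact quantity the fit evaluates — and h(x) > 0 is the
  maximum-entropy site tilt solving Σₓ f_l(x)h(x) = const for every grid
  length (a 9-dimensional convex dual, solved by L-BFGS). The tilt makes
  every unnormalized likelihood column a proper density with one common
  normalizer, so the fit is exactly well-specified on the generated data:
  the label marginal is θ* and the population-level MLE equals θ* (<10⁻³
  residual at the defaults). This is the operational meaning adopted here
  for "sampling from the mixture model with known θ*".
- **lattice**: draw l ~ θ*, then a pair ∝ raw position-pair propensity at
  l (uniform for l = 0). Mechanistically appealing, but the fitted model
  is then misspecified — the unnormalized likelihood tilts the estimate
  toward lengths with larger total propensity; the measured population
  bias at the defaults is max|θ̂−θ*| ≈ 0.2. Kept for studying exactly that
  mismatch.
- **bin**: uniform lattice anchor, bin drawn within the anchor's window
  (the bootstrap protocol); re-centering the analysis window on the
  simulated breakpoint makes this approximately, not exactly, consistent.

True lengths are emitted per deletion in a `true_l` side channel so
evaluation never re-infers them.

What the generator does *not* emulate: sequencing/PCR artifacts, clonal
expansion, deletion-size distributions beyond breakpoint placement,
mtDNA-realistic repeat architecture (unless planted), and heteroplasmy.
Passing the recovery test therefore demonstrates statistical correctness
of the estimator under the model's own sampling assumptions at realistic
scale — not robustness to every property of real catalogs.

## Validation summary

- DP = enumeration oracle on ≥200 random small fragments (10⁻⁹ rel).
- Ensemble symmetry Z(A,B) = Z(B,A); monotone growth of Z under perfect
  extension; N never increases Z; T → 0 and T → ∞ limits.
- Window geometry for the (6329:13993) worked example: L 6229–6429,
  H 13893–14093; l = 5 propensity = explicit 25-duplex sum.
- Bin normalization to 1 (±10⁻¹²), mass conservation, uniform fallback.
- Simulate-then-fit at n = 2000 on the 16-kb defaults: max|θ̂−θ*| ≤ 0.05
  (typical ≈ 0.03; residual spread is genuine MLE variance from
  medium-band component overlap, verified by independent optimizers).
- Estimator SD scales ≈ 1/√n; bootstrap is deterministic given a seed.

## Numerical choices and degenerate inputs

- Linear-space kernel for grid lengths (exact in float64 ≤ ~190 nt
  GC-rich); log-space path for the public per-pair API up to the 200-nt
  cap.
- Summed-area-table rectangle sums can leave tiny negative round-off;
  values are clipped at 0.
- EM renormalizes θ at machine precision each step; mixture likelihoods
  are floored at 10⁻³⁰⁰ against all-zero rows.
- Breakpoint tables: malformed or out-of-range rows are rejected and
  logged with row numbers (accepted + rejected = input rows); p5 = p3 is
  invalid; positions are preserved verbatim (no normalization of
  direct-repeat ambiguity — whether source catalogs normalized theirs is
  unknowable here).
- `flanking_repeat_length` reports, configurably, the identity run
  downstream of (p5, p3), upstream of them, or the maximum of the two
  (default): the literature uses both conventions.

## Known limitations

- The thermodynamic parameterization of the original analysis is not
  public; absolute Z values here may differ by a model-dependent factor.
  Relative propensities and recovered mixture weights — the quantities the
  method actually interprets — are insensitive to global rescaling, but
  per-length weights can shift under a different loop/mismatch model.
- Neighboring medium lengths (10–25 nt) are intrinsically correlated
  components; per-length weights within that band carry more variance than
  the grouped short/medium/long summaries, which are the robust readout.
- The engine holds one summed-area table per (cluster, length) in memory;
  catalogs spanning a whole 16.5-kb genome in one cluster are capped by
  `max_span` (4000 nt per axis) and split automatically, at the cost of
  re-evaluating overlap regions between clusters.
- No salt/Mg²⁺ corrections, no intramolecular structure, no dangling ends.
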