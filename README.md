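# mtmisalign

**Misalignment-length signatures of mitochondrial DNA deletion breakpoints
from DNA hybridization thermodynamics.**

Mitochondrial DNA (mtDNA) deletions — the mutations behind Kearns–Sayre
syndrome, progressive external ophthalmoplegia and much of age-related
mitochondrial decline — are widely believed to arise when single-stranded
mtDNA segments *misalign*: hybridize at a non-allelic position during
double-strand-break repair or replication. Different repair pathways use
characteristically different homology lengths (NHEJ ~0–5 nt, MMEJ ~0–25 nt,
homologous recombination ≥100 nt), so the length of the misaligned duplex
is a mechanistic fingerprint. This package estimates, for any catalog of
deletion breakpoints, **what fraction of deletions is associated with each
misalignment length**, using nothing but the reference sequence and
nearest-neighbor DNA thermodynamics.

## The method

For a deletion with 5′ breakpoint `p5` and 3′ breakpoint `p3` on a circular
mtDNA reference (1-based, L-strand):

1. **Window of analysis.** Take the 201-nt L-strand sequence centered on
   `p5` and the 201-nt H-strand sequence centered on `p3`; together they
   define a 201 × 201 grid of position pairs.
2. **Duplex partition function.** For a candidate misalignment length *l*,
   every position pair (i, j) is overlapped by *l* × *l* duplexes of *l*-nt
   segments. Each duplex is scored by its hybridization partition function

   *Z* = Σ over admissible configurations exp(−ΔG/RT),

   where configurations are non-crossing sets of base pairs organized into
   helices (Watson–Crick stacks and tabulated internal single mismatches,
   Jacobson–Stockmayer loop penalties, duplex initiation and terminal A·T
   terms; unified ΔG°37 parameters at 1 M NaCl). The **propensity** of a
   position pair is the sum of the *l*² duplex partition functions.
3. **Binning.** The window is tiled into 10 × 10-nt bins (20 × 20 = 400
   bins); the **relative breakpoint-bin propensity** *p*<sub>l</sub> is the
   propensity mass of the bin containing the breakpoint divided by the
   window total. *l* = 0 models hybridization-independent formation,
   *p*₀ = 1/400.
4. **Mixture model.** Across a dataset of *n* deletions and the length grid
   *l* ∈ {0, 5, 10, 15, 20, 25, 50, 75, 100}, the weights θ<sub>l</sub>
   (on the probability simplex) maximize

   Σᵢ log Σₗ θₗ *p*<sub>il</sub>,

   via expectation–maximization (the problem is concave over the simplex).
   θ̂ₗ estimates the fraction of deletions associated with length *l*;
   results are summarized as short (0–5 nt), medium (10–25 nt) and long
   (≥50 nt) groups, with parametric-bootstrap standard deviations.

A genome-scale engine evaluates each distinct segment-pair partition
function once per region (numba kernel) and serves every per-breakpoint
map, bin and profile as O(1) rectangle sums from summed-area tables, which
is what makes catalog-scale fits tractable on a laptop.

## Worked example

`examples/02_breakpoint_profile.py` builds a synthetic genome with a 5-nt
perfect direct repeat spanning the breakpoint pair (800:2200) in an
otherwise non-hybridizing background and prints:

```
breakpoint (800:2200), flanking direct repeat = 5 nt
l [nt]   p_l (relative breakpoint-bin propensity)
     0   0.0025
     5   0.9302  ###############################################################
    10   0.5551  ######################################
    15   0.3275  ######################
    20   0.2034  #############
    25   0.1370  #########
    50   0.0373  ##
    75   0.0170  #
   100   0.0097
profile peaks at l = 5 nt: the breakpoint is best explained by a misalignment of that length
(p_5 is 372x the uniform value 1/400)
```

`p_5 = 0.93` means that, at length 5, 93% of the window's hybridization
propensity falls in the breakpoint's own bin — overwhelming evidence for a
5-nt misalignment, against the uniform expectation of 0.25%.

`examples/03_simulate_and_fit.py` closes the loop — it simulates 400
deletions from known weights θ* = (0.2 @ 0, 0.5 @ 5, 0.3 @ 10) and refits:

```
l [nt]   theta*    theta_hat
     0    0.200       0.255
     5    0.500       0.422
    10    0.300       0.323
    20    0.000       0.000
max |theta_hat - theta*| = 0.078
```

at full scale (n = 2000, see below) the recovery error drops under 0.03.
The other examples demonstrate the duplex ensemble itself
(`01_duplex_ensemble.py`, validated against brute-force enumeration) and
bootstrap error bars (`04_bootstrap_uncertainty.py`).

A thin CLI wraps the same library: `mtmisalign fit`, `mtmisalign profile`,
`mtmisalign simulate`, `mtmisalign validate` (see `--help`).

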