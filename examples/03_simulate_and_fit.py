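"""Round trip: simulate an in-silico deletion catalog, refit the mixture.

Draws 400 deletion breakpoints over a 6-kb synthetic genome from a known
mixture of misalignment lengths (50% 5-nt, 30% 10-nt, 20% hybridization-
independent) and fits the mixture model to the simulated catalog.  The
fitted weights estimate the fraction of deletions associated with each
length; at this reduced size they should track the generating weights to
within a few percent (the full-scale validation lives in
scripts/acceptance.py).
"""

import numpy as np

from mtmisalign import (
    LengthGrid,
    PropensityEngine,
    SimulationSpec,
    component_matrix,
    fit_mixture,
    group_weights,
    load_nn_parameters,
    simulate_breakpoints,
    synthetic_genome,
)

spec = SimulationSpec(
    genome_length=6000,
    candidate_region_5=(1000, 1400),
    candidate_region_3=(4000, 4400),
    theta_true={0: 0.2, 5: 0.5, 10: 0.3},
    n=400,
    seed=8,
)
grid = LengthGrid((0, 5, 10, 20))
params = load_nn_parameters()

genome = synthetic_genome(spec)
engine = PropensityEngine(genome, params, grid=grid)
dataset = simulate_breakpoints(genome, spec, params, grid=grid, engine=engine)
fit = fit_mixture(component_matrix(dataset, engine))

print(f"simulated n = {len(dataset)} deletions on a {genome.length}-nt genome")
print("l [nt]   theta*    theta_hat")
for l, th in fit.theta_by_length().items():
    print(f"{l:6d}   {spec.theta_true.get(l, 0.0):6.3f}    {th:8.3f}")
err = max(
    abs(th - spec.theta_true.get(l, 0.0)) for l, th in fit.theta_by_length().items()
)
print(f"\nmax |theta_hat - theta*| = {err:.3f}")
print("grouped weights (short 0-5 / medium 10-25 / long >=50):",
      {k: round(v, 3) for k, v in fit.grouped.items()})
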