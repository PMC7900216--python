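"""Partition function of the duplex ensemble of two short DNA strands.

Builds a 6-nt L-strand fragment and its perfect H-strand complement,
evaluates the hybridization partition function Z (Boltzmann-weighted sum
over every admissible duplex configuration) and the minimum free energy,
then introduces a single internal mismatch and shows the ensemble
destabilization.  The same numbers are recomputed by brute-force
enumeration of all configurations to show the two routes agree.
"""

from mtmisalign import (
    duplex_partition_function,
    enumerate_configurations,
    load_nn_parameters,
    reverse_complement,
)

params = load_nn_parameters()  # unified NN dG37, 1 M NaCl

seqA = "GATCGC"                       # L-strand fragment, 5'->3'
seqB = reverse_complement(seqA)       # perfect H-strand partner

pf = duplex_partition_function(seqA, seqB, params)
configs = enumerate_configurations(seqA, seqB, params)
z_enum = sum(__import__("math").exp(-e / params.RT) for _, e in configs)

print(f"L-strand fragment : 5'-{seqA}-3'")
print(f"H-strand fragment : 5'-{seqB}-3'")
print(f"Z   (dynamic programming) = {pf.Z:.6f}")
print(f"Z   (enumeration, {len(configs):3d} configurations) = {z_enum:.6f}")
print(f"MFE                       = {pf.mfe_dG:+.3f} kcal/mol")

mutated = seqB[:3] + ("A" if seqB[3] != "A" else "C") + seqB[4:]
pf_mm = duplex_partition_function(seqA, mutated, params)
print(f"\nwith one internal mismatch (H-strand {mutated}):")
print(f"Z = {pf_mm.Z:.6f}, MFE = {pf_mm.mfe_dG:+.3f} kcal/mol")
print("-> the mismatch shrinks the ensemble weight: a stability ratio of "
      f"{pf.Z / pf_mm.Z:.1f}x in favor of the perfect duplex.")
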