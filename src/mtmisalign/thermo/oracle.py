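"""Brute-force enumeration of the duplex configuration ensemble.

This is the validation oracle for :func:`duplex_partition_function`: it
explicitly lists every admissible configuration (non-crossing set of base
pairs organized into helices) under exactly the same grammar, scores each
with the same energy terms, and sums the Boltzmann weights.  It is
deliberately independent of the dynamic-programming recursion and is only
usable for tiny fragments (|seqA| * |seqB| <= 64).
"""

from __future__ import annotations

import math
from typing import Iterator

from .params import (
    PAIR_NONE,
    PAIR_TYPE,
    PAIR_WC,
    A,
    T,
    NNParameterSet,
    encode_sequence,
)

MAX_CELLS = 64


def _monotone_chains(n: int, m: int) -> Iterator[tuple[tuple[int, int], ...]]:
    """All non-empty strictly increasing chains of (i, k) cells in an n*m grid."""
    chain: list[tuple[int, int]] = []

    def rec(i0: int, k0: int):
        for i in range(i0, n):
            for k in range(k0, m):
                chain.append((i, k))
                yield tuple(chain)
                yield from rec(i + 1, k + 1)
                chain.pop()

    yield from rec(0, 0)


def configuration_energy(
    chain: tuple[tuple[int, int], ...],
    x,
    z,
    params: NNParameterSet,
) -> float | None:
    """Energy of one candidate configuration, or None if inadmissible.

    ``chain`` lists base pairs (i, k) in the stacked orientation (seqA index,
    reversed-seqB index), strictly increasing in both coordinates.
    """
    estep = params.step_energy_table()
    types = []
    for i, k in chain:
        t = PAIR_TYPE[int(x[i]), int(z[k])]
        if t == PAIR_NONE:
            return None
        types.append(t)

    # split into helices at non-stack gaps and accumulate energy
    energy = params.init_dG37
    helix_start = 0
    for idx in range(1, len(chain) + 1):
        is_break = idx == len(chain)
        if not is_break:
            di = chain[idx][0] - chain[idx - 1][0]
            dk = chain[idx][1] - chain[idx - 1][1]
            if di == 1 and dk == 1:  # stacked: same helix
                e = estep[
                    int(x[chain[idx - 1][0]]),
                    int(x[chain[idx][0]]),
                    int(z[chain[idx - 1][1]]),
                    int(z[chain[idx][1]]),
                ]
                if not math.isfinite(e):
                    return None  # untabulated step (e.g. adjacent mismatches)
                energy += e
                continue
            loop_size = (di - 1) + (dk - 1)
            if loop_size > params.max_loop:
                return None
            energy += params.loop_dG(loop_size)
            is_break = True
        if is_break:
            # helix [helix_start, idx) just ended: check grammar
            if idx - helix_start < 2:
                return None  # lone pair: no stack
            if types[helix_start] != PAIR_WC or types[idx - 1] != PAIR_WC:
                return None  # mismatches cannot terminate a helix
            helix_start = idx

    for end in (0, len(chain) - 1):
        xi = int(x[chain[end][0]])
        if xi == A or xi == T:
            energy += params.terminal_AT_dG37
    return energy


def enumerate_configurations(
    seqA: str, seqB: str, params: NNParameterSet
) -> list[tuple[tuple[tuple[int, int], ...], float]]:
    """All admissible configurations of a tiny duplex, with their energies.

    Returns a list of ``(pairs, dG)`` where ``pairs`` are 0-based
    ``(index in seqA, index in seqB)`` tuples, both strands 5'->3'.
    Raises for fragments with more than 64 cells — this is an oracle, not a
    production path.
    """
    if not seqA or not seqB:
        raise ValueError("sequences must be non-empty")
    if len(seqA) * len(seqB) > MAX_CELLS:
        raise ValueError(
            f"oracle limited to |seqA|*|seqB| <= {MAX_CELLS} "
            f"(got {len(seqA)}x{len(seqB)})"
        )
    x = encode_sequence(seqA)
    z = encode_sequence(seqB)[::-1]
    m = z.size
    out = []
    for chain in _monotone_chains(x.size, m):
        if len(chain) < 2:
            continue
        e = configuration_energy(chain, x, z, params)
        if e is not None:
            pairs = tuple((i, m - 1 - k) for i, k in chain)
            out.append((pairs, e))
    return out


def oracle_partition_function(
    seqA: str, seqB: str, params: NNParameterSet
) -> tuple[float, float]:
    """(Z, mfe_dG) by exhaustive enumeration."""
    configs = enumerate_configurations(seqA, seqB, params)
    if not configs:
        return 0.0, math.inf
    RT = params.RT
    z = sum(math.exp(-e / RT) for _, e in configs)
    return z, min(e for _, e in configs)
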