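"""Ensemble partition function of hybridization between two short DNA strands.

The ensemble ("all feasible duplex configurations") is fixed by an
admissibility grammar:

* antiparallel, intermolecular duplexes only — no hairpins, no pseudoknots;
* base pairs are non-crossing and organized into helices, i.e. maximal runs
  of stacked pairs; every helix has at least two pairs (a lone pair has no
  nearest-neighbor stack energy and is inadmissible);
* a stack is either Watson-Crick/Watson-Crick or a tabulated internal
  single-mismatch context; mismatched pairs therefore never sit at a helix
  end and never stack on one another;
* helices are separated by internal loops/bulges of 1..max_loop total
  unpaired nucleotides, scored by the Jacobson-Stockmayer penalty;
* one duplex-initiation term per configuration and a terminal A:T penalty
  at each end of the configuration; dangling ends are not scored;
* positions pairing with N are unpairable;
* the empty (unhybridized) state is excluded from Z — hybridization-free
  deletion formation is modeled separately as the l = 0 mixture component.

The recursion here runs in log space, so arbitrarily stable long duplexes
(up to the 200-nt cap) cannot overflow; the vectorized genome-scale kernel
in :mod:`mtmisalign._kernels` evaluates the same recursion in linear space,
which is exact for the <= 100-nt analysis grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    PAIR_NONE,
    PAIR_TYPE,
    PAIR_WC,
    A,
    T,
    NNParameterSet,
    encode_sequence,
)

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class PartitionFunctionValue:
    """Boltzmann-weighted ensemble sum and minimum free energy of a duplex.

    ``Z`` is dimensionless; ``Z == 0`` iff no admissible configuration
    exists, in which case ``mfe_dG`` is +inf.  ``log_Z`` is provided for
    overflow-free downstream arithmetic.
    """

    Z: float
    mfe_dG: float
    log_Z: float

    def __post_init__(self) -> None:
        if self.Z < 0:
            raise ValueError("partition function must be non-negative")


def _logaddexp(a: float, b: float) -> float:
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    m = a if a > b else b
    return m + math.log(math.exp(a - m) + math.exp(b - m))


def duplex_partition_function(
    seqA: str, seqB: str, params: NNParameterSet
) -> PartitionFunctionValue:
    """Partition function of the duplex ensemble of two DNA fragments.

    ``seqA`` is the L-strand fragment and ``seqB`` the H-strand fragment,
    both written 5'->3'.  Hybridization is antiparallel: position i of
    ``seqA`` pairing position j of ``seqB`` stacks onto (i+1, j-1).
    """
    if not seqA or not seqB:
        raise ValueError("sequences must be non-empty")
    if len(seqA) > 200 or len(seqB) > 200:
        raise ValueError("fragments longer than 200 nt are not supported")
    x = encode_sequence(seqA)
    z = encode_sequence(seqB)[::-1]  # reversed: pair (i,k) stacks onto (i+1,k+1)
    n, m = x.size, z.size

    RT = params.RT
    estep = params.step_energy_table()
    lstep = np.where(np.isfinite(estep), -estep / RT, _NEG_INF)
    maxloop = params.max_loop
    eloop = np.array([math.inf] + [params.loop_dG(s) for s in range(1, maxloop + 1)])
    lloop = -eloop / RT
    eat = params.terminal_AT_dG37

    # log-space DP; three helix states per cell:
    #   lH1 — helix opened at this (WC) pair, nothing stacked yet
    #   lHx — helix of >=2 pairs whose current last pair is WC (closable)
    #   lHm — helix of >=2 pairs whose current last pair is a mismatch
    lH1 = np.full((n, m), _NEG_INF)
    lHx = np.full((n, m), _NEG_INF)
    lHm = np.full((n, m), _NEG_INF)
    # min-energy counterparts for the MFE
    eH1 = np.full((n, m), math.inf)
    eHx = np.full((n, m), math.inf)
    eHm = np.full((n, m), math.inf)

    log_total = _NEG_INF
    mfe = math.inf
    for i in range(n):
        xi = int(x[i])
        for k in range(m):
            zk = int(z[k])
            ptype = PAIR_TYPE[xi, zk]
            if ptype == PAIR_NONE:
                continue
            if ptype == PAIR_WC:
                at_end = xi == A or xi == T
                lterm = -eat / RT if at_end else 0.0
                eterm = eat if at_end else 0.0
                # open a helix: fresh start, or continuation after a loop
                ls = lterm
                es = eterm
                for li in range(maxloop + 1):
                    ii = i - 1 - li
                    if ii < 0:
                        break
                    for lj in range(maxloop - li + 1):
                        kk = k - 1 - lj
                        if kk < 0:
                            break
                        s = li + lj
                        if s >= 1:
                            ls = _logaddexp(ls, lHx[ii, kk] + lloop[s])
                            es = min(es, eHx[ii, kk] + eloop[s])
                lH1[i, k] = ls
                eH1[i, k] = es
                if i > 0 and k > 0:
                    lw = lstep[int(x[i - 1]), xi, int(z[k - 1]), zk]
                    if lw > _NEG_INF:
                        prev = _logaddexp(
                            _logaddexp(lH1[i - 1, k - 1], lHx[i - 1, k - 1]),
                            lHm[i - 1, k - 1],
                        )
                        lHx[i, k] = prev + lw
                        eHx[i, k] = (
                            min(eH1[i - 1, k - 1], eHx[i - 1, k - 1], eHm[i - 1, k - 1])
                            - lw * RT
                        )
                # close the configuration at this WC pair
                log_total = _logaddexp(log_total, lHx[i, k] + lterm)
                mfe = min(mfe, eHx[i, k] + eterm)
            else:  # mismatch: only extends a helix, preceded by a WC pair
                if i > 0 and k > 0:
                    lw = lstep[int(x[i - 1]), xi, int(z[k - 1]), zk]
                    if lw > _NEG_INF:
                        prev = _logaddexp(lH1[i - 1, k - 1], lHx[i - 1, k - 1])
                        lHm[i, k] = prev + lw
                        eHm[i, k] = min(eH1[i - 1, k - 1], eHx[i - 1, k - 1]) - lw * RT

    if log_total == _NEG_INF:
        return PartitionFunctionValue(Z=0.0, mfe_dG=math.inf, log_Z=_NEG_INF)
    log_Z = log_total - params.init_dG37 / RT
    mfe_dG = mfe + params.init_dG37
    return PartitionFunctionValue(
        Z=math.exp(log_Z) if log_Z < 709 else math.inf,
        mfe_dG=mfe_dG,
        log_Z=log_Z,
    )
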