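"""Misalignment propensities within the window of analysis.

For a deletion breakpoint (p5, p3) the analysis considers the
(2W+1) x (2W+1) grid of position pairs formed by a 201-nt L-strand window
centered on p5 and a 201-nt H-strand window centered on p3 (default
W = 100).  The propensity of a position pair at misalignment length l is
the sum of duplex partition functions over the l x l segment pairs that
overlap the pair; bin propensities sum these over 10 x 10-nt patches and
are normalized over the window.

Segments overlapping a position pair may extend beyond the window edge;
they are read from the circular genome, not truncated — the window bounds
which position pairs are scored, not which sequence content is visible.

The :class:`PropensityEngine` evaluates partition functions once per
distinct (segment, segment) pair over a region covering many breakpoints
(the pre-computed-arc strategy) and serves per-breakpoint maps, bins and
per-length profiles as O(1) rectangle sums from summed-area tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import pf_matrix
from .genome import Breakpoint, MtGenome, complement, reverse_complement
from .thermo.duplex import duplex_partition_function
from .thermo.params import PAIR_TYPE, NNParameterSet, encode_sequence

logger = logging.getLogger("mtmisalign")

DEFAULT_LENGTHS = (0, 5, 10, 15, 20, 25, 50, 75, 100)


@dataclass(frozen=True)
class LengthGrid:
    """The grid of candidate misalignment lengths (nt), always including 0."""

    lengths: tuple[int, ...] = DEFAULT_LENGTHS

    def __post_init__(self) -> None:
        ls = self.lengths
        if 0 not in ls:
            raise ValueError("length grid must contain 0 (the uniform component)")
        if any(b <= a for a, b in zip(ls, ls[1:])):
            raise ValueError("length grid must be strictly increasing")

    def __iter__(self):
        return iter(self.lengths)

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def positive(self) -> tuple[int, ...]:
        return tuple(l for l in self.lengths if l > 0)

    def validate_window(self, W: int) -> None:
        if max(self.lengths) > 2 * W + 1:
            raise ValueError(
                f"max grid length {max(self.lengths)} exceeds window width {2*W+1}"
            )


@dataclass(frozen=True)
class AnalysisWindow:
    """The two-dimensional window of analysis for one breakpoint.

    ``L_window`` is the reference (L-strand) sequence p5-W..p5+W read 5'->3';
    ``H_window`` is the H-strand sequence covering p3-W..p3+W, i.e. the
    reverse complement of the reference slice, read 5'->3'.  Offsets -W..+W
    on either axis map to reference positions p5+i and p3+j; the center
    offset pair (0, 0) is the breakpoint itself.  Interval endpoints are
    reported in wrapped 1-based reference coordinates.
    """

    genome: MtGenome
    breakpoint: Breakpoint
    W: int
    L_window: str
    H_window: str
    L_interval: tuple[int, int]
    H_interval: tuple[int, int]

    @property
    def width(self) -> int:
        return 2 * self.W + 1


def extract_window(genome: MtGenome, bp: Breakpoint, W: int = 100) -> AnalysisWindow:
    """Extract the (2W+1)-nt L- and H-strand windows around a breakpoint."""
    if W < 1:
        raise ValueError("W must be >= 1")
    if 2 * W + 1 > genome.length:
        raise ValueError(
            f"window of width {2*W+1} does not fit genome of length {genome.length}"
        )
    bp.validate(genome)
    L = genome.length
    wrap = lambda pos: (pos - 1) % L + 1
    l_seq = _tiled_slice(genome, bp.p5 - W, 2 * W + 1)
    h_ref = _tiled_slice(genome, bp.p3 - W, 2 * W + 1)
    return AnalysisWindow(
        genome=genome,
        breakpoint=bp,
        W=W,
        L_window=l_seq,
        H_window=reverse_complement(h_ref),
        L_interval=(wrap(bp.p5 - W), wrap(bp.p5 + W)),
        H_interval=(wrap(bp.p3 - W), wrap(bp.p3 + W)),
    )


@dataclass
class PropensityMap:
    """Per-position-pair propensities for one breakpoint and one length."""

    l: int
    values: np.ndarray  # (2W+1, 2W+1), entry (i+W, j+W) = offsets (i, j)
    breakpoint: Breakpoint | None = None

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("propensity map entries must be finite and >= 0")


@dataclass
class BinnedPropensityMap:
    """b x b-nt binned propensities and their window-normalized values."""

    l: int
    bin_size: int
    bins: np.ndarray
    relative_bins: np.ndarray
    breakpoint_bin: tuple[int, int]
    uniform_fallback: bool = False


def position_pair_propensity(
    window: AnalysisWindow,
    i: int,
    j: int,
    l: int,
    params: NNParameterSet,
) -> float:
    """Propensity of one position pair: the sum of l*l duplex partition
    functions of the l-nt L-segments containing p5+i and the l-nt H-segments
    containing p3+j.

    This is the direct (per-duplex) reference evaluation; use a
    :class:`PropensityEngine` for whole maps.
    """
    if l < 1:
        raise ValueError(
            "l must be >= 1; the l = 0 component is uniform by definition "
            "and handled at the bin level"
        )
    if not (-window.W <= i <= window.W and -window.W <= j <= window.W):
        raise ValueError("offsets outside the window of analysis")
    g, bp = window.genome, window.breakpoint
    total = 0.0
    for a in range(l):
        segL = _tiled_slice(g, bp.p5 + i - l + 1 + a, l)
        for b in range(l):
            segH = reverse_complement(_tiled_slice(g, bp.p3 + j - l + 1 + b, l))
            total += duplex_partition_function(segL, segH, params).Z
    return total


def _tiled_slice(genome: MtGenome, start: int, width: int) -> str:
    """Circular slice that tolerates any 1-based start and width > L."""
    L = genome.length
    s = (start - 1) % L
    reps = (s + width + L - 1) // L
    return (genome.sequence * reps)[s : s + width]


class PropensityEngine:
    """Shared partition-function tables over genomic regions.

    Breakpoints are clustered by proximity; for every cluster and length l
    the engine evaluates the partition function of all distinct l x l
    segment pairs of the covering regions once (numba kernel), stores a
    summed-area table, and answers per-breakpoint propensity maps, binned
    maps and length profiles as rectangle sums.  Results are bit-identical
    to the direct evaluation and deterministic.

    ``pad`` widens the covered regions (in nt) so that nearby breakpoints
    not in the preparing set — e.g. bootstrap resamples within the original
    windows — can also be served.
    """

    def __init__(
        self,
        genome: MtGenome,
        params: NNParameterSet,
        grid: LengthGrid | None = None,
        W: int = 100,
        bin_size: int = 10,
        max_span: int = 4000,
        pad: int = 0,
    ) -> None:
        if (2 * W) % bin_size != 0:
            raise ValueError("bin size must divide the tiled span 2W")
        self.genome = genome
        self.params = params
        self.grid = grid or LengthGrid()
        self.grid.validate_window(W)
        self.W = W
        self.bin_size = bin_size
        self.max_span = max_span
        self.pad = pad
        self.n_bins = (2 * W) // bin_size
        self._clusters: list[tuple[int, int, int, int]] = []
        self._sats: dict[tuple[int, int], tuple[np.ndarray, int, int]] = {}
        # kernel-ready parameter tables
        self._wstep = params.step_weight_table()
        self._loopw = params.loop_weights()
        self._wat = params.terminal_weights()
        self._initw = params.init_weight()

    # -- preparation --------------------------------------------------------

    def prepare(self, breakpoints: list[Breakpoint]) -> None:
        """Declare the breakpoints this engine will serve (builds clusters)."""
        for bp in breakpoints:
            bp.validate(self.genome)
        pts = sorted({(bp.p5, bp.p3) for bp in breakpoints})
        for lo5, hi5, group in self._split_1d([p[0] for p in pts], pts, axis=0):
            for lo3, hi3, _ in self._split_1d([p[1] for p in group], group, axis=1):
                self._clusters.append((lo5, hi5, lo3, hi3))
        logger.debug(
            "engine prepared: %d breakpoint pairs in %d cluster(s)",
            len(pts), len(self._clusters),
        )

    def _split_1d(self, coords, pts, axis):
        order = np.argsort(coords, kind="stable")
        groups = []
        cur: list = []
        lo = None
        for idx in order:
            c = coords[idx]
            if lo is None or c - lo <= self.max_span:
                if lo is None:
                    lo = c
                cur.append(pts[idx])
            else:
                groups.append((lo, max(p[axis] for p in cur), cur))
                lo, cur = c, [pts[idx]]
        if cur:
            groups.append((lo, max(p[axis] for p in cur), cur))
        return groups

    def _cluster_for(self, bp: Breakpoint) -> tuple[int, int, int, int]:
        slack = self.pad
        for lo5, hi5, lo3, hi3 in self._clusters:
            if lo5 - slack <= bp.p5 <= hi5 + slack and lo3 - slack <= bp.p3 <= hi3 + slack:
                return (lo5, hi5, lo3, hi3)
        # not covered: register a dedicated single-breakpoint cluster
        cluster = (bp.p5, bp.p5, bp.p3, bp.p3)
        self._clusters.append(cluster)
        return cluster

    def _sat_for(self, cluster: tuple[int, int, int, int], l: int):
        key = (cluster, l)
        if key in self._sats:
            return self._sats[key]
        lo5, hi5, lo3, hi3 = cluster
        pad = self.pad
        # L-side segment starts u in [lo5-pad - W - l + 1, hi5+pad + W]
        SA = lo5 - pad - self.W - l + 1
        widthA = (hi5 - lo5 + 2 * pad) + 2 * self.W + 2 * l - 1
        SB = lo3 - pad - self.W - l + 1
        widthB = (hi3 - lo3 + 2 * pad) + 2 * self.W + 2 * l - 1
        xa = encode_sequence(_tiled_slice(self.genome, SA, widthA))
        # stacked orientation: base-wise complement of the reference slice
        zb = encode_sequence(complement(_tiled_slice(self.genome, SB, widthB)))
        D = pf_matrix(
            xa, zb, l, self._wstep, PAIR_TYPE, self._loopw,
            self.params.max_loop, self._wat, self._initw,
        )
        sat = np.zeros((D.shape[0] + 1, D.shape[1] + 1))
        np.cumsum(np.cumsum(D, axis=0), axis=1, out=sat[1:, 1:])
        self._sats[key] = (sat, SA, SB)
        logger.debug(
            "cluster %s l=%d: %dx%d segment pairs evaluated", cluster, l, *D.shape
        )
        return self._sats[key]

    # -- queries ------------------------------------------------------------

    def map_for(self, bp: Breakpoint, l: int) -> PropensityMap:
        """The full (2W+1)^2 propensity map of one breakpoint at length l."""
        if l < 1:
            raise ValueError("l must be >= 1")
        sat, SA, SB = self._sat_for(self._cluster_for(bp), l)
        W = self.W
        n = 2 * W + 1
        r0 = bp.p5 - W - l + 1 - SA  # D-row of the first segment start for i=-W
        c0 = bp.p3 - W - l + 1 - SB
        if r0 < 0 or c0 < 0 or r0 + n + l - 1 > sat.shape[0] - 1 or c0 + n + l - 1 > sat.shape[1] - 1:
            raise ValueError(
                f"breakpoint ({bp.p5}:{bp.p3}) outside the prepared regions; "
                "call prepare() with it or increase pad"
            )
        # values[i, j] = sum of D over the l x l start rectangle
        values = (
            sat[r0 + l : r0 + l + n, c0 + l : c0 + l + n]
            - sat[r0 : r0 + n, c0 + l : c0 + l + n]
            - sat[r0 + l : r0 + l + n, c0 : c0 + n]
            + sat[r0 : r0 + n, c0 : c0 + n]
        )
        # clip tiny negative round-off from the subtraction
        np.clip(values, 0.0, None, out=values)
        return PropensityMap(l=l, values=values, breakpoint=bp)

    def bins_for(self, bp: Breakpoint, l: int) -> BinnedPropensityMap:
        return bin_map(self.map_for(bp, l), self.bin_size)

    def pair_propensity(self, p5: int, p3: int, l: int) -> float:
        """Propensity of the exact position pair (p5, p3) at length l."""
        bp = Breakpoint(p5=p5, p3=p3)
        sat, SA, SB = self._sat_for(self._cluster_for(bp), l)
        r0 = p5 - l + 1 - SA
        c0 = p3 - l + 1 - SB
        val = float(
            sat[r0 + l, c0 + l] - sat[r0, c0 + l] - sat[r0 + l, c0] + sat[r0, c0]
        )
        return max(val, 0.0)  # clip round-off from the SAT subtraction

    def profile(self, bp: Breakpoint) -> np.ndarray:
        """Relative breakpoint-bin propensity p_l for every grid length.

        p_0 is the uniform value 1/(n_bins^2); for l >= 1 it is the
        normalized propensity of the bin containing the breakpoint.
        """
        out = np.empty(len(self.grid))
        for idx, l in enumerate(self.grid):
            if l == 0:
                out[idx] = 1.0 / self.n_bins**2
            else:
                binned = self.bins_for(bp, l)
                out[idx] = binned.relative_bins[binned.breakpoint_bin]
        return out


def propensity_map(
    window: AnalysisWindow, l: int, params: NNParameterSet
) -> PropensityMap:
    """Full propensity map of one window (one-off engine underneath)."""
    engine = PropensityEngine(window.genome, params, W=window.W)
    engine.prepare([window.breakpoint])
    return engine.map_for(window.breakpoint, l)


def bin_map(pmap: PropensityMap, b: int = 10) -> BinnedPropensityMap:
    """Aggregate a propensity map into b x b-nt bins and normalize.

    The (2W+1)-nt axes are tiled with 2W/b bins covering offsets -W..W-1;
    the single trailing offset +W is dropped, giving the 20 x 20 = 400-bin
    geometry (and the uniform value 1/400 for l = 0) at the defaults.  The
    breakpoint (offset 0, 0) falls in bin (W//b, W//b).  An all-zero map
    (possible on pathological input) falls back to the uniform distribution
    with a logged warning so downstream likelihoods stay finite.
    """
    n = pmap.values.shape[0]
    W = (n - 1) // 2
    if (2 * W) % b != 0:
        raise ValueError(f"bin size {b} does not divide the tiled span {2*W}")
    k = (2 * W) // b
    core = pmap.values[: 2 * W, : 2 * W]
    bins = core.reshape(k, b, k, b).sum(axis=(1, 3))
    total = bins.sum()
    if total > 0:
        rel = bins / total
        fallback = False
    else:
        logger.warning(
            "all-zero propensity map at l=%d; falling back to uniform bins", pmap.l
        )
        rel = np.full((k, k), 1.0 / k**2)
        fallback = True
    return BinnedPropensityMap(
        l=pmap.l,
        bin_size=b,
        bins=bins,
        relative_bins=rel,
        breakpoint_bin=(W // b, W // b),
        uniform_fallback=fallback,
    )


def breakpoint_profile(
    genome: MtGenome,
    bp: Breakpoint,
    grid: LengthGrid | None = None,
    params: NNParameterSet | None = None,
    W: int = 100,
    b: int = 10,
    engine: PropensityEngine | None = None,
) -> dict[int, float]:
    """Relative breakpoint-bin propensity as a function of length.

    Returns {l: p_l} over the grid; the argmax length is the single-deletion
    misalignment-length call.
    """
    if engine is None:
        if params is None:
            raise ValueError("params required when no engine is given")
        engine = PropensityEngine(genome, params, grid=grid, W=W, bin_size=b)
        engine.prepare([bp])
    values = engine.profile(bp)
    return dict(zip(engine.grid.lengths, values.tolist()))


def export_map_tsv(pmap: PropensityMap, path) -> None:
    """Write a propensity map as a TSV matrix (rows = L offsets -W..W)."""
    np.savetxt(path, pmap.values, delimiter="\t", fmt="%.8g")


def export_bins_tsv(binned: BinnedPropensityMap, path) -> None:
    np.savetxt(path, binned.relative_bins, delimiter="\t", fmt="%.8g")
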