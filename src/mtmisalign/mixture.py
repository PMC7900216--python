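"""Finite mixture model over misalignment lengths, fitted by maximum likelihood.

Each deletion i contributes a likelihood sum_l theta_l * P[i, l], where
P[i, l] is the relative breakpoint-bin propensity of deletion i at grid
length l (the l = 0 column is the uniform 1/400).  The weights theta live
on the probability simplex; theta_l estimates the fraction of deletions in
the dataset associated with misalignments of length l.  The concave
log-likelihood is maximized by expectation-maximization with closed-form
updates; uncertainty comes from a parametric-within-window bootstrap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import Breakpoint, BreakpointDataset
from .propensity import LengthGrid, PropensityEngine

logger = logging.getLogger("mtmisalign")

#: grouped-summary bands (nt): short 0-5, medium 10-25, long >= 50
GROUP_BANDS = {"short": (0, 5), "medium": (10, 25), "long": (50, 10**9)}


@dataclass
class ComponentMatrix:
    """Per-deletion, per-length relative breakpoint-bin propensities."""

    P: np.ndarray  # (n, K), entries in (0, 1]
    grid: LengthGrid
    uniform_rows: np.ndarray | None = None  # rows that fell back to uniform bins

    def __post_init__(self) -> None:
        if self.P.ndim != 2 or self.P.shape[1] != len(self.grid):
            raise ValueError("component matrix shape does not match the grid")
        if not np.all(np.isfinite(self.P)) or np.any(self.P < 0):
            raise ValueError("component matrix entries must be finite and >= 0")

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class MixtureFit:
    """Maximum-likelihood mixture weights and diagnostics."""

    grid: LengthGrid
    theta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    non_identifiable: bool = False
    grouped: dict[str, float] = field(default_factory=dict)
    sd_grouped: dict[str, float] | None = None
    sd_theta: np.ndarray | None = None
    B: int | None = None
    seed: int | None = None

    def theta_by_length(self) -> dict[int, float]:
        return dict(zip(self.grid.lengths, self.theta.tolist()))

    def to_json(self, path: str | Path, config: dict | None = None) -> None:
        doc = {
            "schema": "mtmisalign.fit/1",
            "grid": list(self.grid.lengths),
            "theta": self.theta.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "non_identifiable": self.non_identifiable,
            "grouped": self.grouped,
            "sd_grouped": self.sd_grouped,
            "sd_theta": None if self.sd_theta is None else self.sd_theta.tolist(),
            "B": self.B,
            "seed": self.seed,
            "config": config or {},
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def component_matrix(
    dataset: BreakpointDataset,
    engine: PropensityEngine,
) -> ComponentMatrix:
    """Assemble P[i, l] by evaluating each deletion's per-length profile."""
    if len(dataset) == 0:
        raise ValueError("empty breakpoint dataset")
    engine.prepare(dataset.breakpoints)
    n, K = len(dataset), len(engine.grid)
    P = np.empty((n, K))
    uniform = np.zeros(n, dtype=bool)
    for i, bp in enumerate(dataset):
        P[i] = engine.profile(bp)
        if np.allclose(P[i], P[i, 0]):
            uniform[i] = True
    # individual entries may be 0 (a length that cannot explain the bin);
    # the constant l = 0 column keeps every row's mixture likelihood positive
    if np.any(P < 0):
        raise ValueError("negative component entries")
    if uniform.any():
        logger.warning(
            "%d deletion(s) with no thermodynamic signal (uniform rows)",
            int(uniform.sum()),
        )
    return ComponentMatrix(P=P, grid=engine.grid, uniform_rows=uniform)


def _em(P: np.ndarray, theta0: np.ndarray, tol: float, max_iter: int):
    theta = theta0.copy()
    prev = -np.inf
    for it in range(1, max_iter + 1):
        mix = np.maximum(P @ theta, 1e-300)  # (n,)
        ll = float(np.log(mix).sum())
        if ll + 1e-12 < prev:  # EM guarantees monotonicity; guard regardless
            raise RuntimeError(f"log-likelihood decreased at iteration {it}")
        if it > 1 and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            return theta, ll, it, True
        prev = ll
        resp = P * theta  # (n, K) responsibilities, unnormalized
        resp /= mix[:, None]
        theta = resp.mean(axis=0)
        theta = np.clip(theta, 0.0, None)
        theta /= theta.sum()
    return theta, prev, max_iter, False


def fit_mixture(
    P: ComponentMatrix | np.ndarray,
    grid: LengthGrid | None = None,
    tol: float = 1e-9,
    max_iter: int = 10_000,
    n_starts: int = 1,
    seed: int | None = None,
) -> MixtureFit:
    """Maximize sum_i log(sum_l theta_l P[i,l]) over the simplex via EM.

    The problem is concave over the simplex, so the EM fixed point from the
    uniform start is the global optimum; ``n_starts > 1`` adds random
    Dirichlet starts as a ridge guard and checks that all optima agree.
    Ties (e.g. all rows uniform) resolve to the uniform-start fixed point.
    """
    if isinstance(P, ComponentMatrix):
        grid = P.grid
        mat = P.P
    else:
        mat = np.asarray(P, dtype=float)
        if grid is None:
            raise ValueError("grid required when P is a bare array")
    if mat.ndim != 2 or mat.shape[1] != len(grid):
        raise ValueError("component matrix shape does not match the grid")
    if not np.all(np.isfinite(mat)) or np.any(mat < 0):
        raise ValueError("component matrix entries must be finite and >= 0")
    n, K = mat.shape
    if K == 1:
        theta = np.ones(1)
        ll = float(np.log(mat[:, 0]).sum())
        fit = MixtureFit(grid=grid, theta=theta, loglik=ll, n_iter=0, converged=True)
        fit.grouped = group_weights(theta, grid)
        return fit

    theta0 = np.full(K, 1.0 / K)
    theta, ll, n_iter, conv = _em(mat, theta0, tol, max_iter)
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            t0 = rng.dirichlet(np.ones(K))
            t_alt, ll_alt, _, _ = _em(mat, t0, tol, max_iter)
            if ll_alt > ll + 1e-6 * (abs(ll) + 1.0):
                logger.warning(
                    "multi-start found a better optimum (%.6g > %.6g); "
                    "likelihood surface may be ridged", ll_alt, ll,
                )
                theta, ll = t_alt, ll_alt

    fit = MixtureFit(
        grid=grid, theta=theta, loglik=ll, n_iter=n_iter, converged=conv,
        non_identifiable=_near_singular(mat, theta),
    )
    fit.grouped = group_weights(theta, grid)
    return fit


def _near_singular(P: np.ndarray, theta: np.ndarray, rtol: float = 1e-8) -> bool:
    """Flag a flat likelihood ridge: near-singular projected Hessian."""
    mix = P @ theta
    U = P / mix[:, None]  # d loglik / d theta = column sums of U
    H = U.T @ U  # negative Hessian on the affine hull
    K = H.shape[0]
    # project onto the simplex tangent space (sum of coordinates = 0)
    B = np.eye(K)[:, : K - 1] - 1.0 / K
    Ht = B.T @ H @ B
    ev = np.linalg.eigvalsh(Ht)
    return bool(ev[0] < rtol * max(ev[-1], 1e-300))


def group_weights(theta: np.ndarray, grid: LengthGrid) -> dict[str, float]:
    """Short (0-5 nt), medium (10-25 nt) and long (>= 50 nt) weight sums."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(grid),):
        raise ValueError("theta does not match the grid")
    out = {}
    for name, (lo, hi) in GROUP_BANDS.items():
        out[name] = float(
            sum(t for t, l in zip(theta, grid.lengths) if lo <= l <= hi)
        )
    return out


def resample_dataset(
    dataset: BreakpointDataset,
    engine: PropensityEngine,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> BreakpointDataset:
    """One parametric-within-window resample of a dataset.

    For each original deletion, draw a length l ~ theta; for l = 0 draw a
    bin uniformly, otherwise draw a bin within that deletion's own window
    with probability equal to its relative bin propensity at l.  The
    simulated breakpoint is placed at the bin center, preserving each
    deletion's local sequence context.
    """
    grid = engine.grid
    b = engine.bin_size
    W = engine.W
    k = engine.n_bins
    new_bps: list[Breakpoint] = []
    true_l: list[int] = []
    L = dataset.genome.length
    for bp in dataset:
        l = int(rng.choice(grid.lengths, p=theta))
        if l == 0:
            flat = int(rng.integers(0, k * k))
        else:
            rel = engine.bins_for(bp, l).relative_bins.ravel()
            flat = int(rng.choice(rel.size, p=rel / rel.sum()))
        r, c = divmod(flat, k)
        # center of a b-wide bin covering offsets [r*b - W, r*b - W + b - 1]
        di = r * b - W + b // 2
        dj = c * b - W + b // 2
        p5 = (bp.p5 + di - 1) % L + 1
        p3 = (bp.p3 + dj - 1) % L + 1
        if p5 == p3:  # degenerate corner on tiny genomes; nudge one position
            p3 = p3 % L + 1
        new_bps.append(Breakpoint(p5=p5, p3=p3, dataset=bp.dataset, species=bp.species))
        true_l.append(l)
    return BreakpointDataset(
        name=dataset.name, genome=dataset.genome,
        breakpoints=new_bps, true_lengths=true_l,
    )


def bootstrap_sd(
    fit: MixtureFit,
    dataset: BreakpointDataset,
    engine: PropensityEngine,
    B: int = 100,
    seed: int = 0,
) -> MixtureFit:
    """Bootstrap standard deviations of the grouped (and per-l) weights.

    Generates B in-silico datasets of the same size from the fitted mixture
    (each deletion resampled within its own window), refits each, and
    returns the fit with the sample SDs attached.  Grouped SDs are computed
    on grouped weights per replicate.  Fully reproducible given ``seed``.

    The engine must have been prepared with ``pad >= W + bin_size`` so the
    shifted replicate breakpoints stay inside the covered regions.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    thetas = np.empty((B, len(fit.grid)))
    grouped = np.empty((B, len(GROUP_BANDS)))
    names = list(GROUP_BANDS)
    for rep in range(B):
        ds_rep = resample_dataset(dataset, engine, fit.theta, rng)
        P_rep = component_matrix(ds_rep, engine)
        f_rep = fit_mixture(P_rep)
        thetas[rep] = f_rep.theta
        grouped[rep] = [f_rep.grouped[nm] for nm in names]
    fit.sd_theta = thetas.std(axis=0, ddof=1)
    fit.sd_grouped = dict(zip(names, grouped.std(axis=0, ddof=1).tolist()))
    fit.B = B
    fit.seed = seed
    return fit


def export_fit_tsv(fit: MixtureFit, dataset_name: str, path: str | Path) -> None:
    """Flat TSV: dataset, l, theta, group."""
    def band(l: int) -> str:
        for name, (lo, hi) in GROUP_BANDS.items():
            if lo <= l <= hi:
                return name
        return "unassigned"

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("dataset\tl\ttheta\tgroup\n")
        for l, t in zip(fit.grid.lengths, fit.theta):
            fh.write(f"{dataset_name}\t{l}\t{t:.6f}\t{band(l)}\n")
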