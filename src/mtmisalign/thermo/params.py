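"""Nearest-neighbor thermodynamic parameter sets for DNA duplex hybridization.

The default set (``unified_37C``) combines the unified Watson-Crick stack
free energies with published internal single-mismatch nearest-neighbor
parameters, duplex initiation and terminal A:T penalties, all as dG at
37 C and 1 M NaCl, with no salt correction.  Internal loops and bulges are
scored by a Jacobson-Stockmayer size penalty dG(s) = a + c*ln(s) with a hard
admissibility cutoff ``max_loop`` on the total number of unpaired
nucleotides per loop.  All values live in a packaged plain-text table and
are swappable via :func:`NNParameterSet.from_tsv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

# base encoding used throughout the package
BASES = "ACGTN"
A, C, G, T, N = range(5)
ENCODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_CODE = np.array([T, G, C, A, N], dtype=np.uint8)

#: pair-type codes used by the kernels
PAIR_NONE, PAIR_WC, PAIR_MM = 0, 1, 2

_PACKAGED = {"unified_37C"}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes."""
    try:
        return np.frombuffer(
            bytes(ENCODE[b] for b in seq), dtype=np.uint8
        ).copy()
    except KeyError as exc:
        raise ValueError(f"illegal symbol {exc} in sequence") from exc


def _pair_type_table() -> np.ndarray:
    t = np.zeros((5, 5), dtype=np.uint8)
    for x in range(4):
        for z in range(4):
            t[x, z] = PAIR_WC if z == COMPLEMENT_CODE[x] else PAIR_MM
    return t


PAIR_TYPE = _pair_type_table()


@dataclass(frozen=True)
class NNParameterSet:
    """A nearest-neighbor dG37 parameter set plus the ensemble grammar knobs.

    ``stack_dG37`` and ``mismatch_dG37`` are keyed by duplex step contexts in
    the standard ``XY/WZ`` notation (top strand 5'-XY-3' over bottom strand
    3'-WZ-5').  Each physical stack is stored once; the rotated reading
    (``ZW/YX``) denotes the same stack and is expanded internally.
    """

    name: str
    stack_dG37: dict[str, float]
    mismatch_dG37: dict[str, float]
    init_dG37: float
    terminal_AT_dG37: float
    loop_a: float = 3.2
    loop_c: float = 1.5
    max_loop: int = 6
    temperature: float = 310.15  # kelvin
    R: float = 0.0019872  # kcal/mol/K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.max_loop < 0:
            raise ValueError("max_loop must be >= 0")
        missing = _WC_CONTEXTS - set(self._expand(self.stack_dG37))
        if missing:
            raise ValueError(f"Watson-Crick stack table incomplete: {sorted(missing)}")

    # -- derived quantities -------------------------------------------------

    @property
    def RT(self) -> float:
        return self.R * self.temperature

    def loop_dG(self, size: int) -> float:
        """Free-energy penalty of an internal loop/bulge of `size` unpaired nt."""
        if size < 1:
            raise ValueError("loop size must be >= 1")
        if size > self.max_loop:
            return math.inf
        return self.loop_a + self.loop_c * math.log(size)

    @staticmethod
    def _expand(table: dict[str, float]) -> dict[str, float]:
        """Add the 180-degree rotated reading of every context."""
        out = dict(table)
        for key, val in table.items():
            x1, x2, y1, y2 = key[0], key[1], key[3], key[4]
            out.setdefault(f"{y2}{y1}/{x2}{x1}", val)
        return out

    def step_energy_table(self) -> np.ndarray:
        """dG37 of each duplex step, indexed [x1, x2, z1, z2] by base code.

        ``x`` indexes the top-strand bases 5'->3'; ``z`` the bottom-strand
        bases 3'->5' (so z1 pairs x1).  Inadmissible steps (untabulated
        contexts, two adjacent mismatches, anything involving N) are +inf.
        """
        tab = np.full((5, 5, 5, 5), np.inf)
        merged = self._expand(self.stack_dG37) | self._expand(self.mismatch_dG37)
        for key, val in merged.items():
            x1, x2, y1, y2 = (ENCODE[b] for b in (key[0], key[1], key[3], key[4]))
            tab[x1, x2, y1, y2] = val
        return tab

    def step_weight_table(self) -> np.ndarray:
        """Boltzmann factors exp(-dG/RT) of step_energy_table (0 = forbidden)."""
        e = self.step_energy_table()
        w = np.zeros_like(e)
        finite = np.isfinite(e)
        w[finite] = np.exp(-e[finite] / self.RT)
        return w

    def loop_weights(self) -> np.ndarray:
        """exp(-loop_dG(s)/RT) for s = 0..max_loop (index 0 unused, set to 0)."""
        w = np.zeros(self.max_loop + 1)
        for s in range(1, self.max_loop + 1):
            w[s] = math.exp(-self.loop_dG(s) / self.RT)
        return w

    def terminal_weights(self) -> np.ndarray:
        """Per-base terminal-pair factor: exp(-terminal_AT/RT) for A or T."""
        w = np.ones(5)
        w[A] = w[T] = math.exp(-self.terminal_AT_dG37 / self.RT)
        return w

    def init_weight(self) -> float:
        return math.exp(-self.init_dG37 / self.RT)

    def with_temperature(self, kelvin: float) -> "NNParameterSet":
        """Same dG37 tables re-weighted at another temperature (Boltzmann only)."""
        return replace(self, temperature=kelvin)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "NNParameterSet":
        stack: dict[str, float] = {}
        mismatch: dict[str, float] = {}
        scalars: dict[str, float] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("section\t"):
                continue
            section, context, value = line.split("\t")
            if section == "stack":
                stack[context] = float(value)
            elif section == "mismatch":
                mismatch[context] = float(value)
            elif section in ("meta", "init", "loop"):
                scalars[context] = float(value)
            else:
                raise ValueError(f"unknown section {section!r} in {path}")
        return cls(
            name=name or Path(path).stem,
            stack_dG37=stack,
            mismatch_dG37=mismatch,
            init_dG37=scalars["duplex"],
            terminal_AT_dG37=scalars["terminal_AT"],
            loop_a=scalars["loop_a"],
            loop_c=scalars["loop_c"],
            max_loop=int(scalars["max_loop"]),
            temperature=scalars["temperature_K"],
            R=scalars["R_kcal_mol_K"],
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = ["section\tcontext\tvalue"]
        rows.append(f"meta\ttemperature_K\t{self.temperature:g}")
        rows.append(f"meta\tR_kcal_mol_K\t{self.R:g}")
        rows += [f"stack\t{k}\t{v:.4f}" for k, v in sorted(self.stack_dG37.items())]
        rows += [f"mismatch\t{k}\t{v:.4f}" for k, v in sorted(self.mismatch_dG37.items())]
        rows.append(f"init\tduplex\t{self.init_dG37:.4f}")
        rows.append(f"init\tterminal_AT\t{self.terminal_AT_dG37:.4f}")
        rows.append(f"loop\tloop_a\t{self.loop_a:.4f}")
        rows.append(f"loop\tloop_c\t{self.loop_c:.4f}")
        rows.append(f"loop\tmax_loop\t{self.max_loop}")
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


_WC_CONTEXTS = {
    "AA/TT", "AT/TA", "TA/AT", "CA/GT", "GT/CA",
    "CT/GA", "GA/CT", "CG/GC", "GC/CG", "GG/CC",
}


def load_nn_parameters(name: str = "unified_37C") -> NNParameterSet:
    """Load a packaged parameter set by label."""
    if name not in _PACKAGED:
        raise ValueError(
            f"unknown parameter set {name!r}; available: {sorted(_PACKAGED)}"
        )
    ref = resources.files("mtmisalign.thermo") / "data" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return NNParameterSet.from_tsv(path, name=name)
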