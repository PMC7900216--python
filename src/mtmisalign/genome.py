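"""Circular mitochondrial genomes and deletion-breakpoint catalogs.

All coordinates in this package are 1-based and inclusive on the reference
(L-strand) sequence, matching the numbering conventions of the deposited
mitochondrial references (e.g. the human rCRS).  The heavy strand is the
reverse complement of the reference and is never stored explicitly; windows
on the H-strand are represented as reference-coordinate intervals plus an
orientation flag.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger("mtmisalign")

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeError(ValueError):
    """Raised for malformed genome input."""


class BreakpointError(ValueError):
    """Raised for malformed breakpoint input."""


@dataclass(frozen=True)
class MtGenome:
    """A circular mitochondrial reference sequence (L-strand, 5'->3')."""

    identifier: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise GenomeError(
                f"genome {self.identifier!r} contains illegal symbol(s) "
                f"{sorted(bad)}; only A, C, G, T and N are accepted"
            )
        if not self.sequence:
            raise GenomeError(f"genome {self.identifier!r} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Breakpoint:
    """A deletion breakpoint: 5' and 3' junction positions on the reference."""

    p5: int
    p3: int
    dataset: str = ""
    species: str = ""

    def validate(self, genome: MtGenome) -> None:
        for name, pos in (("p5", self.p5), ("p3", self.p3)):
            if not 1 <= pos <= genome.length:
                raise BreakpointError(
                    f"{name}={pos} outside genome of length {genome.length}"
                )
        if self.p5 == self.p3:
            raise BreakpointError(f"degenerate breakpoint p5 == p3 == {self.p5}")


@dataclass
class BreakpointDataset:
    """An ordered collection of breakpoints that share one reference genome."""

    name: str
    genome: MtGenome
    breakpoints: list[Breakpoint] = field(default_factory=list)
    # optional per-breakpoint ground-truth misalignment length (simulations)
    true_lengths: list[int] | None = None

    def __len__(self) -> int:
        return len(self.breakpoints)

    def __iter__(self):
        return iter(self.breakpoints)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N is its own complement."""
    bad = set(seq) - _ALPHABET
    if bad:
        raise GenomeError(f"illegal symbol(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Base-wise complement without reversal."""
    bad = set(seq) - _ALPHABET
    if bad:
        raise GenomeError(f"illegal symbol(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)


def read_genome(path: str | Path, record_id: str | None = None) -> MtGenome:
    """Read one record of a FASTA file as a circular mtDNA reference.

    Uppercases the sequence.  RNA (U) and IUPAC degeneracy codes other than
    N are rejected with a message naming the offending symbol.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeError(f"no FASTA records in {path}")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise GenomeError(
                f"record {record_id!r} not found in {path}; "
                f"available: {[r.id for r in records]}"
            )
        record = matches[0]
    else:
        record = records[0]
    seq = str(record.seq).upper()
    if not seq:
        raise GenomeError(f"record {record.id!r} in {path} is empty")
    bad = set(seq) - _ALPHABET
    if bad:
        raise GenomeError(
            f"record {record.id!r} contains unsupported symbol(s) {sorted(bad)}; "
            "only A, C, G, T and N are accepted (degenerate codes beyond N "
            "and RNA 'U' must be resolved upstream)"
        )
    return MtGenome(identifier=record.id, sequence=seq)


def circular_slice(genome: MtGenome, start: int, end: int) -> str:
    """Inclusive 1-based slice that wraps through the origin when start > end.

    Result length is ``(end - start) mod L + 1``.  ``start == end`` yields a
    single nucleotide; a full-length slice returns the whole sequence.
    """
    L = genome.length
    for name, pos in (("start", start), ("end", end)):
        if not 1 <= pos <= L:
            raise BreakpointError(f"{name}={pos} outside genome of length {L}")
    if start <= end:
        return genome.sequence[start - 1 : end]
    return genome.sequence[start - 1 :] + genome.sequence[:end]


def circular_slice_unbounded(genome: MtGenome, start: int, width: int) -> str:
    """Slice of given width starting at (possibly out-of-range) 1-based start.

    Positions are reduced modulo the genome length, so callers may address
    windows that overhang the origin with ordinary arithmetic
    (e.g. start = p5 - W - l + 1 may be <= 0).
    """
    L = genome.length
    if width < 1:
        raise ValueError("width must be >= 1")
    if width > L:
        raise BreakpointError(f"requested width {width} exceeds genome length {L}")
    s = (start - 1) % L
    e = s + width
    if e <= L:
        return genome.sequence[s:e]
    return genome.sequence[s:] + genome.sequence[: e - L]


def load_breakpoints(
    path: str | Path,
    genome: MtGenome,
    *,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> dict[str, BreakpointDataset]:
    """Load a delimited breakpoint table, grouped by dataset label.

    The table must have a header.  Default column names are ``dataset``,
    ``species``, ``p5`` and ``p3``; ``columns`` remaps them (e.g.
    ``{"p5": "5p_breakpoint"}``).  Comma and tab delimiters are
    auto-detected unless ``delimiter`` is given.  Malformed rows and rows
    with out-of-range positions are rejected and logged with their row
    number; accepted + rejected always equals the number of input rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"breakpoint table not found: {path}")
    colmap = {"dataset": "dataset", "species": "species", "p5": "p5", "p3": "p3"}
    if columns:
        colmap.update(columns)

    text = path.read_text(encoding="utf-8").splitlines()
    if not text:
        raise BreakpointError(f"empty breakpoint table: {path}")
    if delimiter is None:
        delimiter = "\t" if "\t" in text[0] else ","
    header = [h.strip() for h in text[0].split(delimiter)]
    try:
        idx = {key: header.index(col) for key, col in colmap.items()}
    except ValueError as exc:
        raise BreakpointError(
            f"missing column in {path}: {exc}; header was {header}"
        ) from exc

    datasets: dict[str, BreakpointDataset] = {}
    n_ok = n_bad = 0
    for row_no, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delimiter)]
        try:
            bp = Breakpoint(
                p5=int(fields[idx["p5"]]),
                p3=int(fields[idx["p3"]]),
                dataset=fields[idx["dataset"]],
                species=fields[idx["species"]],
            )
            bp.validate(genome)
        except (ValueError, IndexError) as exc:
            n_bad += 1
            logger.warning("rejected row %d of %s: %s", row_no, path.name, exc)
            continue
        n_ok += 1
        ds = datasets.setdefault(
            bp.dataset, BreakpointDataset(name=bp.dataset, genome=genome)
        )
        ds.breakpoints.append(bp)

    if not datasets:
        raise BreakpointError(f"no valid breakpoints loaded from {path}")
    for name, ds in sorted(datasets.items()):
        logger.info("dataset %-24s %6d breakpoints", name, len(ds))
    logger.info(
        "loaded %d breakpoints in %d dataset(s); rejected %d row(s)",
        n_ok, len(datasets), n_bad,
    )
    return datasets


def flanking_repeat_length(
    genome: MtGenome,
    bp: Breakpoint,
    max_len: int = 30,
    *,
    convention: str = "both",
) -> int:
    """Length of the longest perfect direct repeat flanking a breakpoint.

    ``convention`` selects which flank comparison is reported:

    - ``"downstream"``: identity run of the sequences starting at p5 and p3
      (both read 5'->3' on the L-strand);
    - ``"upstream"``: identity run of the sequences ending at p5-1 and p3-1;
    - ``"both"`` (default): the maximum of the two.

    Returns 0 when the flanks share no sequence, capped at ``max_len``.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    bp.validate(genome)

    def run_forward(a: int, b: int) -> int:
        n = 0
        while n < max_len:
            ca = circular_slice_unbounded(genome, a + n, 1)
            cb = circular_slice_unbounded(genome, b + n, 1)
            if ca != cb or ca == "N":
                break
            n += 1
        return n

    def run_backward(a: int, b: int) -> int:
        n = 0
        while n < max_len:
            ca = circular_slice_unbounded(genome, a - 1 - n, 1)
            cb = circular_slice_unbounded(genome, b - 1 - n, 1)
            if ca != cb or ca == "N":
                break
            n += 1
        return n

    if convention == "downstream":
        return run_forward(bp.p5, bp.p3)
    if convention == "upstream":
        return run_backward(bp.p5, bp.p3)
    if convention == "both":
        return max(run_forward(bp.p5, bp.p3), run_backward(bp.p5, bp.p3))
    raise ValueError(f"unknown flank convention {convention!r}")


def write_genome_fasta(genome: MtGenome, path: str | Path, width: int = 70) -> None:
    """Write a genome as single-record FASTA."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f">{genome.identifier}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_breakpoints(
    datasets: Iterable[BreakpointDataset] | BreakpointDataset,
    path: str | Path,
) -> None:
    """Write breakpoint datasets in the TSV dialect that load_breakpoints reads.

    Simulated datasets carry their ground-truth misalignment length in an
    extra ``true_l`` column (ignored by the loader).
    """
    if isinstance(datasets, BreakpointDataset):
        datasets = [datasets]
    datasets = list(datasets)
    any_truth = any(ds.true_lengths is not None for ds in datasets)
    with Path(path).open("w", encoding="utf-8") as fh:
        cols = ["dataset", "species", "p5", "p3"] + (["true_l"] if any_truth else [])
        fh.write("\t".join(cols) + "\n")
        for ds in datasets:
            truths: Sequence[int | str]
            if ds.true_lengths is not None:
                truths = ds.true_lengths
            else:
                truths = [""] * len(ds)
            for bp, tl in zip(ds.breakpoints, truths):
                row = [bp.dataset or ds.name, bp.species, str(bp.p5), str(bp.p3)]
                if any_truth:
                    row.append(str(tl))
                fh.write("\t".join(row) + "\n")


def configure_logging(verbose: bool = False) -> None:
    """Send package log lines to stderr (one line per dataset during loads)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
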