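"""BED and chrom.sizes input/output and strand-aware read-start extraction.

DNaseI-seq signal lives at read start sites: the 5' end of each mapped
read approximates a DNaseI cut site. This module reduces BED intervals to
those start coordinates (with an optional user offset, so the same caller
can serve ChIP-seq or FAIRE-seq data), reads UCSC-style chrom.sizes
tables, and serialises called peaks back to BED.

Coordinates are 0-based half-open throughout, as in BED itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class ReadStart(NamedTuple):
    """A mapped read reduced to its strand-aware start coordinate."""

    chrom: str
    pos: int
    strand: str


@dataclass(frozen=True)
class Peak:
    """A called open-chromatin region.

    ``start``/``end`` are the union of the flagged central windows,
    ``summit`` the centre of the bin with the highest corrected read
    density.  Scores: ``max_corrected_density`` in reads per central bin,
    ``min_tail_probability`` the smallest background tail mass over the
    run's bins.
    """

    chrom: str
    start: int
    end: int
    max_corrected_density: float
    min_tail_probability: float
    summit: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak start {self.start} >= end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak [{self.start}, {self.end})"
            )
        if not (0.0 <= self.min_tail_probability <= 1.0):
            raise ValueError("min_tail_probability outside [0, 1]")


class ChromSizes:
    """Ordered chromosome-name -> length mapping (the sampling universe)."""

    def __init__(self, entries: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        self._entries: dict[str, int] = {}
        items = entries.items() if isinstance(entries, Mapping) else entries
        for name, length in items:
            if name in self._entries:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"non-positive length {length} for {name!r}")
            self._entries[name] = length

    def __getitem__(self, name: str) -> int:
        return self._entries[name]

    def __contains__(self, name: object) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChromSizes):
            return NotImplemented
        return list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"ChromSizes({self._entries!r})"

    def items(self):
        return self._entries.items()


@dataclass
class ChromReads:
    """Read starts on one chromosome, sorted by position."""

    pos: np.ndarray  # int64, ascending
    strand: np.ndarray  # '<U1'

    def __len__(self) -> int:
        return len(self.pos)

    def __iter__(self):
        return zip(self.pos.tolist(), self.strand.tolist())


def read_start(start: int, end: int, strand: str, offset: int = 0) -> int:
    """Strand-aware start of a BED interval, shifted ``offset`` bp toward 3'.

    Plus-strand (and strandless) reads start at the BED start; minus-strand
    reads start at the last covered base (BED end - 1), their 5' end. The
    offset is added on '+' and subtracted on '-'.
    """
    if strand == "-":
        return (end - 1) - offset
    return start + offset


def read_bed_reads(
    path,
    offset: int = 0,
    chrom_sizes: ChromSizes | None = None,
) -> dict[str, ChromReads]:
    """Parse a BED3+ file into per-chromosome sorted read starts.

    Strand is taken from column 6 when present, else '+'. When
    ``chrom_sizes`` is given, reads on unknown chromosomes and reads whose
    shifted start falls outside the chromosome are dropped (not clamped)
    and the counts logged.

    Raises ``ValueError`` naming the offending line for non-integer
    coordinates, start >= end, or an illegal strand symbol.
    """
    by_chrom: dict[str, tuple[list[int], list[str]]] = {}
    n_dropped_chrom = 0
    n_dropped_bounds = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in STRANDS:
                raise ValueError(f"line {lineno}: bad strand {strand!r}")
            pos = read_start(start, end, strand, offset)
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    n_dropped_chrom += 1
                    continue
                if not (0 <= pos < chrom_sizes[chrom]):
                    n_dropped_bounds += 1
                    continue
            elif pos < 0:
                n_dropped_bounds += 1
                continue
            slot = by_chrom.setdefault(chrom, ([], []))
            slot[0].append(pos)
            slot[1].append(strand)
    if n_dropped_chrom:
        logger.info("dropped %d reads on chromosomes absent from sizes table",
                    n_dropped_chrom)
    if n_dropped_bounds:
        logger.info("dropped %d reads with start outside chromosome bounds",
                    n_dropped_bounds)
    out: dict[str, ChromReads] = {}
    for chrom, (positions, strands) in by_chrom.items():
        pos_arr = np.asarray(positions, dtype=np.int64)
        strand_arr = np.asarray(strands, dtype="<U1")
        order = np.argsort(pos_arr, kind="stable")
        out[chrom] = ChromReads(pos_arr[order], strand_arr[order])
    return out


def read_chrom_sizes(path) -> ChromSizes:
    """Read a two-column UCSC-style chrom.sizes file, preserving order."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected name and length")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer length") from exc
            if length <= 0:
                raise ValueError(f"line {lineno}: non-positive length {length}")
            entries.append((fields[0], length))
    try:
        return ChromSizes(entries)
    except ValueError as exc:
        raise ValueError(str(exc)) from None


def write_peaks_bed(
    peaks: Iterable[Peak],
    path,
    score_mode: str = "density",
    header_params: Mapping[str, object] | None = None,
) -> None:
    """Write peaks as BED6 plus a 7th summit column.

    Score column is the peak's maximum corrected read density
    (``score_mode='density'``) or -log10 of its minimum background tail
    probability (``score_mode='probability'``). Peaks must arrive sorted
    by (chrom, start) and non-overlapping within a chromosome.
    """
    if score_mode not in ("density", "probability"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    peaks = list(peaks)
    prev: Peak | None = None
    seen_chroms: set[str] = set()
    for pk in peaks:
        if prev is not None and pk.chrom == prev.chrom:
            if pk.start < prev.start:
                raise ValueError("peaks not sorted by start within chromosome")
            if pk.start < prev.end:
                raise ValueError(
                    f"overlapping peaks on {pk.chrom}: "
                    f"[{prev.start},{prev.end}) and [{pk.start},{pk.end})"
                )
        elif prev is not None:
            if pk.chrom in seen_chroms:
                raise ValueError(f"peaks for {pk.chrom} are not contiguous")
            seen_chroms.add(prev.chrom)
        prev = pk
    with open(path, "w") as fh:
        fh.write("# kdepeaks peaks: chrom start end name score strand summit\n")
        if header_params:
            rendered = " ".join(f"{k}={v}" for k, v in header_params.items())
            fh.write(f"# parameters: {rendered}\n")
        fh.write(f"# score_mode: {score_mode}\n")
        for k, pk in enumerate(peaks, start=1):
            if score_mode == "density":
                score = f"{pk.max_corrected_density:g}"
            else:
                p = max(pk.min_tail_probability, 1e-300)
                score = f"{-math.log10(p):g}"
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak_{k}\t{score}\t.\t"
                f"{pk.summit}\n"
            )


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")
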