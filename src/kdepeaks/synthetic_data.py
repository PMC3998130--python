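"""Seeded synthetic DNaseI-seq datasets with known enriched regions.

Background read starts are a homogeneous Poisson process along each
chromosome; inside each spiked region, extra starts are added at rate
``(enrichment_factor - 1) * background_rate``, so the total rate there is
``enrichment_factor * background_rate`` and the expected corrected read
density of a fully covered central bin is analytically
``(enrichment_factor - 1) * background_rate * central_size``. Strand is
an independent fair coin; reads have fixed length. The generator captures
the rate structure a peak caller must resolve, not DNaseI cut-site
sequence bias, mappability or duplicate-read artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from intervaltree import IntervalTree

from .genomic_io import ChromSizes, Peak


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters plus the spiked regions (the ground truth).

    ``background_rate`` is expected read starts per bp; ``regions`` are
    ``(chrom, start, end, enrichment_factor)`` with factor > 1, inside
    chromosome bounds and mutually non-overlapping.
    """

    chrom_sizes: ChromSizes
    background_rate: float
    regions: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        object.__setattr__(self, "regions", tuple(
            (str(c), int(s), int(e), float(f)) for c, s, e, f in self.regions
        ))
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, factor in self.regions:
            if chrom not in self.chrom_sizes:
                raise ValueError(f"region chromosome {chrom!r} not in sizes")
            if not (0 <= start < end <= self.chrom_sizes[chrom]):
                raise ValueError(
                    f"region [{start},{end}) outside {chrom} bounds"
                )
            if factor <= 1:
                raise ValueError("enrichment_factor must exceed 1")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping regions on {chrom}")


class BedRead(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str


def generate_reads(
    truth: SyntheticTruth,
    read_length: int = 36,
) -> list[BedRead]:
    """Draw one synthetic dataset; deterministic for a fixed truth.seed.

    Per chromosome the background start count is Poisson(rate * length)
    with uniform positions; each region adds Poisson((factor - 1) * rate
    * span) starts uniform within it. A '+' read spans
    [pos, pos + read_length), a '-' read [pos - read_length + 1, pos + 1)
    (the start is its 5' end); reads that would extend past a chromosome
    edge are dropped.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    rng = np.random.default_rng(truth.seed)
    records: list[BedRead] = []
    regions_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, start, end, factor in truth.regions:
        regions_by_chrom.setdefault(chrom, []).append((start, end, factor))

    for chrom, length in truth.chrom_sizes.items():
        starts_list = []
        n_bg = rng.poisson(truth.background_rate * length)
        if n_bg:
            starts_list.append(rng.integers(0, length, size=n_bg))
        for r_start, r_end, factor in regions_by_chrom.get(chrom, []):
            extra_rate = (factor - 1.0) * truth.background_rate
            n_extra = rng.poisson(extra_rate * (r_end - r_start))
            if n_extra:
                starts_list.append(rng.integers(r_start, r_end, size=n_extra))
        if not starts_list:
            continue
        starts = np.concatenate(starts_list)
        strands = rng.random(starts.size) < 0.5
        for pos, minus in zip(starts.tolist(), strands.tolist()):
            if minus:
                b_start, b_end = pos - read_length + 1, pos + 1
            else:
                b_start, b_end = pos, pos + read_length
            if b_start < 0 or b_end > length:
                continue
            records.append(BedRead(chrom, b_start, b_end, "", 0,
                                   "-" if minus else "+"))

    order = {name: i for i, name in enumerate(truth.chrom_sizes)}
    records.sort(key=lambda r: (order[r.chrom], r.start, r.end, r.strand))
    return [r._replace(name=f"read_{k}") for k, r in enumerate(records, 1)]


def write_reads_bed(records: list[BedRead], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t"
                     f"{r.strand}\n")


def write_truth_regions(truth: SyntheticTruth, path) -> None:
    """Tab-separated region table: chrom, start, end, enrichment_factor."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tenrichment_factor\n")
        for chrom, start, end, factor in truth.regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{factor:g}\n")


def read_truth_regions(path) -> list[tuple[str, int, int, float]]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, factor = line.split("\t")
            regions.append((chrom, int(start), int(end), float(factor)))
    return regions


@dataclass
class RecoveryReport:
    """How called peaks line up with spiked truth regions.

    A region is *recovered* when any peak overlaps it by >= 1 bp; a peak
    is *unique* (a false positive against the truth) when it overlaps no
    region. ``unique_percent`` is None when there are no peaks.
    """

    n_regions: int
    n_recovered: int
    n_peaks: int
    n_unique_peaks: int
    best_overlap: dict = field(default_factory=dict)

    @property
    def recovered_percent(self) -> float | None:
        if self.n_regions == 0:
            return None
        return 100.0 * self.n_recovered / self.n_regions

    @property
    def unique_percent(self) -> float | None:
        if self.n_peaks == 0:
            return None
        return 100.0 * self.n_unique_peaks / self.n_peaks


def truth_overlap_report(
    peaks: list[Peak],
    truth: SyntheticTruth,
) -> RecoveryReport:
    """Score peak recovery of the spiked regions (interval-tree overlap)."""
    trees: dict[str, IntervalTree] = {}
    for pk in peaks:
        trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end)

    n_recovered = 0
    best_overlap: dict[tuple[str, int, int], int] = {}
    region_trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _ in truth.regions:
        region_trees.setdefault(chrom, IntervalTree()).addi(start, end)
        hits = trees[chrom].overlap(start, end) if chrom in trees else ()
        best = max(
            (min(end, iv.end) - max(start, iv.begin) for iv in hits),
            default=0,
        )
        best_overlap[(chrom, start, end)] = best
        if best >= 1:
            n_recovered += 1

    n_unique = sum(
        1 for pk in peaks
        if pk.chrom not in region_trees
        or not region_trees[pk.chrom].overlap(pk.start, pk.end)
    )
    return RecoveryReport(
        n_regions=len(truth.regions),
        n_recovered=n_recovered,
        n_peaks=len(peaks),
        n_unique_peaks=n_unique,
        best_overlap=best_overlap,
    )
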