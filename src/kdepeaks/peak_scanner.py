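"""Genome scan in overlapping dual bins and merging of flagged bins into peaks.

Every chromosome is tiled with bin centres at ``background_size/2``,
stepping ``step`` bp (default 100, a third of the central bin, so each
position is covered by several central windows). Bins whose corrected
read density exceeds the dataset-specific threshold are flagged; maximal
runs of flagged bins with overlapping or abutting central windows become
peaks, scored by their maximum corrected density and minimum tail
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np

from .background_model import (
    BackgroundModel,
    BinGeometry,
    BinSignal,
    build_background_model,
    find_threshold,
    sample_random_sites,
    tail_probability,
    _positions,
)
from .genomic_io import ChromSizes, Peak

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Scan geometry, step and the corrected-density threshold to apply."""

    geometry: BinGeometry
    threshold: float
    step: int = 100
    p_cutoff: float = 0.001

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.step > self.geometry.central_size:
            raise ValueError(
                f"step {self.step} larger than central bin "
                f"{self.geometry.central_size}; scan bins must overlap"
            )


def scan_chromosome(
    reads,
    chrom_length: int,
    config: ScanConfig,
    model: BackgroundModel,
    chrom: str = "",
) -> list[BinSignal]:
    """Return the bins whose corrected read density exceeds the threshold.

    ``reads`` is a sorted array of read-start positions (or ``ChromReads``).
    Chromosomes shorter than the background bin yield an empty list with a
    logged skip. Each returned ``BinSignal`` carries its tail probability
    under ``model``.
    """
    geom = config.geometry
    bg = geom.background_size
    if chrom_length < bg:
        logger.info("chromosome %s (%d bp) shorter than background bin; "
                    "skipped", chrom or "?", chrom_length)
        return []
    pos = _positions(reads)
    centers = np.arange(bg // 2, chrom_length - (bg - bg // 2) + 1,
                        config.step, dtype=np.int64)
    c_half = geom.central_size // 2
    b_half = bg // 2
    cc = (np.searchsorted(pos, centers - c_half + geom.central_size, "left")
          - np.searchsorted(pos, centers - c_half, "left"))
    bc = (np.searchsorted(pos, centers - b_half + bg, "left")
          - np.searchsorted(pos, centers - b_half, "left"))
    corrected = cc - bc * geom.expected_ratio
    flagged = np.flatnonzero(corrected > config.threshold)
    if flagged.size == 0:
        return []
    tails = tail_probability(model, corrected[flagged])
    tails = np.atleast_1d(tails)
    return [
        BinSignal(
            chrom=chrom,
            center=int(centers[i]),
            central_count=int(cc[i]),
            background_count=int(bc[i]),
            corrected_density=float(corrected[i]),
            tail_probability=float(t),
        )
        for i, t in zip(flagged.tolist(), tails.tolist())
    ]


def merge_bins_to_peaks(
    flagged: list[BinSignal],
    geometry: BinGeometry,
) -> list[Peak]:
    """Merge runs of flagged bins with overlapping/abutting central windows.

    Peak extent is the union of the run's central windows; the summit is
    the centre of the bin with the maximum corrected density (leftmost on
    ties). A gap of at least 1 bp between central windows splits peaks.
    """
    if not flagged:
        return []
    chroms = {b.chrom for b in flagged}
    if len(chroms) > 1:
        raise ValueError(f"flagged bins span multiple chromosomes: {chroms}")
    chrom = flagged[0].chrom
    flagged = sorted(flagged, key=lambda b: b.center)

    peaks: list[Peak] = []
    run: list[BinSignal] = []
    run_end = None

    def close_run() -> None:
        best = max(run, key=lambda b: b.corrected_density)  # max() keeps leftmost tie
        start = geometry.central_window(run[0].center)[0]
        end = geometry.central_window(run[-1].center)[1]
        min_tail = min(
            (b.tail_probability for b in run if b.tail_probability is not None),
            default=None,
        )
        peaks.append(Peak(
            chrom=chrom,
            start=start,
            end=end,
            max_corrected_density=best.corrected_density,
            min_tail_probability=min_tail if min_tail is not None else 0.0,
            summit=best.center,
        ))

    for b in flagged:
        w_start, w_end = geometry.central_window(b.center)
        if run and w_start > run_end:
            close_run()
            run = []
        run.append(b)
        run_end = w_end if not run[:-1] else max(run_end, w_end)
    close_run()
    return peaks


class PeakCallResult(NamedTuple):
    """Outcome of an end-to-end peak-calling run."""

    model: BackgroundModel
    threshold: float
    peaks: list[Peak]
    summary: dict


def call_peaks(
    reads_by_chrom: Mapping,
    chrom_sizes: ChromSizes,
    n_sites: int = 50_000,
    geometry: BinGeometry | None = None,
    h: float = 1.0,
    p_cutoff: float = 0.001,
    step: int = 100,
    seed: int = 0,
) -> PeakCallResult:
    """Full pipeline: sample background, fit KDE, derive threshold, scan, merge.

    Returns the fitted model, the derived corrected-density threshold,
    peaks sorted by (chrom, start), and a summary dict reporting the
    number of sites drawn, retained after overlap discarding, the
    threshold, and the peak count.
    """
    geometry = geometry or BinGeometry()
    sites = sample_random_sites(chrom_sizes, n_sites, geometry, seed)
    model = build_background_model(reads_by_chrom, sites, geometry, h)
    threshold = find_threshold(model, p_cutoff)
    config = ScanConfig(geometry=geometry, threshold=threshold,
                        step=step, p_cutoff=p_cutoff)
    peaks: list[Peak] = []
    for chrom, length in chrom_sizes.items():
        reads = reads_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        flagged = scan_chromosome(reads, length, config, model, chrom=chrom)
        peaks.extend(merge_bins_to_peaks(flagged, geometry))
    order = {name: i for i, name in enumerate(chrom_sizes)}
    peaks.sort(key=lambda p: (order[p.chrom], p.start))
    summary = {
        "n_sites_drawn": n_sites,
        "n_sites_retained": model.n,
        "threshold": threshold,
        "p_cutoff": p_cutoff,
        "n_peaks": len(peaks),
    }
    logger.info("background: %d/%d sites retained; threshold %.4f; %d peaks",
                model.n, n_sites, threshold, len(peaks))
    return PeakCallResult(model, threshold, peaks, summary)
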