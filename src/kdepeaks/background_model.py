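"""Dataset-specific background model for corrected read densities.

The signal statistic is the *corrected read density*: the read-start
count in a small central bin minus the count expected there from the
surrounding background bin (central nested in background, shared
midpoint).  Sampling that statistic at random non-overlapping genomic
sites gives an empirical null; a Gaussian kernel density estimate with
fixed bandwidth h smooths it,

    f(x) = (1/(n h)) * sum_i K((x - x_i) / h),    K = standard normal pdf,

and the peak-calling threshold is the smallest corrected density whose
upper-tail mass under f drops below a chosen cutoff (default P < 0.001).
Because the null is re-sampled per dataset, the threshold adapts to each
dataset's signal-to-noise ratio.
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .genomic_io import ChromReads, ChromSizes

logger = logging.getLogger(__name__)

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class BinGeometry:
    """Nested dual-bin geometry: a central bin centred in a background bin.

    Defaults: 300 bp central, 3000 bp background. A bin of width w
    centred at c spans [c - w//2, c - w//2 + w).
    """

    central_size: int = 300
    background_size: int = 3000

    def __post_init__(self) -> None:
        if self.central_size <= 0 or self.background_size <= 0:
            raise ValueError("bin sizes must be positive")
        if self.background_size <= self.central_size:
            raise ValueError("background bin must be larger than central bin")

    @property
    def expected_ratio(self) -> float:
        """Fraction of background reads expected in the central bin."""
        return self.central_size / self.background_size

    def central_window(self, center: int) -> tuple[int, int]:
        left = center - self.central_size // 2
        return left, left + self.central_size

    def background_window(self, center: int) -> tuple[int, int]:
        left = center - self.background_size // 2
        return left, left + self.background_size


@dataclass(frozen=True)
class BinSignal:
    """One dual-bin measurement at a genomic site."""

    chrom: str
    center: int
    central_count: int
    background_count: int
    corrected_density: float
    tail_probability: float | None = None

    def __post_init__(self) -> None:
        if self.central_count > self.background_count:
            raise ValueError("central count exceeds background count")


@dataclass(frozen=True)
class BackgroundModel:
    """Sampled corrected read densities plus the KDE bandwidth.

    ``n == len(samples)``; ``n == 1`` is tolerated for unit testing but
    ``build_background_model`` requires at least 2 retained sites.
    """

    samples: np.ndarray
    h: float = 1.0
    n: int = field(init=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "n", samples.size)
        if self.n < 1:
            raise ValueError("background model needs at least one sample")
        if self.h <= 0:
            raise ValueError("bandwidth h must be positive")

    def export(self, samples_path, sidecar_path, p_cutoff=None, threshold=None):
        """Dump samples (one per line) and a JSON sidecar for audits."""
        np.savetxt(samples_path, self.samples, fmt="%.10g")
        meta = {"n": int(self.n), "h": self.h}
        if p_cutoff is not None:
            meta["p_cutoff"] = p_cutoff
        if threshold is not None:
            meta["threshold"] = threshold
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
            fh.write("\n")


def sample_random_sites(
    chrom_sizes: ChromSizes,
    n_sites: int,
    geometry: BinGeometry,
    seed: int,
) -> list[tuple[str, int]]:
    """Draw random bin centres genome-wide and discard overlapping sites.

    Centres are uniform over valid placements (background bin fully inside
    a chromosome), chromosomes weighted by their valid-centre count. A
    single pass in draw order then discards any site whose background bin
    overlaps an earlier retained site on the same chromosome; no
    replacement draws are made, so fewer than ``n_sites`` may survive.
    Deterministic for a fixed seed.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    bg = geometry.background_size
    names: list[str] = []
    lows: list[int] = []
    counts: list[int] = []
    for name, length in chrom_sizes.items():
        n_valid = length - bg + 1
        if n_valid <= 0:
            logger.info("chromosome %s (%d bp) shorter than background bin; "
                        "excluded from sampling", name, length)
            continue
        names.append(name)
        lows.append(bg // 2)
        counts.append(n_valid)
    if not names:
        raise ValueError("no chromosome can host a background bin")

    rng = np.random.default_rng(seed)
    weights = np.asarray(counts, dtype=float)
    chrom_idx = rng.choice(len(names), size=n_sites, p=weights / weights.sum())
    u = rng.random(n_sites)
    lows_arr = np.asarray(lows)
    counts_arr = np.asarray(counts)
    centers = lows_arr[chrom_idx] + np.floor(
        u * counts_arr[chrom_idx]
    ).astype(np.int64)

    retained: list[tuple[str, int]] = []
    by_chrom: dict[str, list[int]] = {}
    for ci, center in zip(chrom_idx.tolist(), centers.tolist()):
        name = names[ci]
        kept = by_chrom.setdefault(name, [])
        # background bins [c-bg//2, c-bg//2+bg) overlap iff |c - c'| < bg
        j = bisect.bisect_left(kept, center)
        if j > 0 and center - kept[j - 1] < bg:
            continue
        if j < len(kept) and kept[j] - center < bg:
            continue
        kept.insert(j, center)
        retained.append((name, center))
    return retained


def count_read_starts(positions: np.ndarray, start: int, end: int) -> int:
    """Number of read starts in the half-open window [start, end).

    ``positions`` must be sorted ascending (the caller's contract).
    """
    if start >= end:
        raise ValueError(f"empty window [{start}, {end})")
    lo, hi = np.searchsorted(positions, [start, end], side="left")
    return int(hi - lo)


def corrected_read_density(
    central_count: int,
    background_count: int,
    geometry: BinGeometry,
) -> float:
    """Central count minus the count expected from the background bin.

    The expectation scales the background count by central_size /
    background_size; the result may be negative in read-poor sites.
    """
    if central_count > background_count:
        raise ValueError(
            f"central count {central_count} exceeds background count "
            f"{background_count}; central bin must nest in background bin"
        )
    return central_count - background_count * geometry.expected_ratio


def _positions(reads) -> np.ndarray:
    if isinstance(reads, ChromReads):
        return reads.pos
    return np.asarray(reads, dtype=np.int64)


def build_background_model(
    chrom_reads,
    sites: list[tuple[str, int]],
    geometry: BinGeometry,
    h: float = 1.0,
) -> BackgroundModel:
    """Measure corrected read density at each sampled site and wrap the KDE.

    ``chrom_reads`` maps chromosome -> sorted read-start positions (plain
    arrays or ``ChromReads``). Chromosomes with no reads count zero.
    """
    if not sites:
        raise ValueError("site list is empty")
    if len(sites) < 2:
        raise ValueError(
            "fewer than 2 sampled sites after discarding; use a larger "
            "genome or more sites"
        )
    empty = np.empty(0, dtype=np.int64)
    samples = np.empty(len(sites), dtype=float)
    for i, (chrom, center) in enumerate(sites):
        pos = _positions(chrom_reads[chrom]) if chrom in chrom_reads else empty
        cs, ce = geometry.central_window(center)
        bs, be = geometry.background_window(center)
        cc = count_read_starts(pos, cs, ce)
        bc = count_read_starts(pos, bs, be)
        samples[i] = corrected_read_density(cc, bc, geometry)
    return BackgroundModel(samples=samples, h=h)


def kde_density(model: BackgroundModel, x) -> np.ndarray | float:
    """Gaussian-kernel density estimate f(x) of the background samples."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    u = (x_arr[:, None] - model.samples[None, :]) / model.h
    f = np.exp(-0.5 * u * u).sum(axis=1) / (model.n * model.h * _SQRT_2PI)
    return float(f[0]) if np.isscalar(x) or np.ndim(x) == 0 else f


def tail_probability(model: BackgroundModel, x) -> np.ndarray | float:
    """Upper-tail mass P(X >= x) under the background KDE.

    Each Gaussian kernel contributes its survival function in closed
    form: P(X >= x) = (1/n) sum_i Phi((x_i - x) / h).
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    p = ndtr((model.samples[None, :] - x_arr[:, None]) / model.h).mean(axis=1)
    return float(p[0]) if np.isscalar(x) or np.ndim(x) == 0 else p


def find_threshold(
    model: BackgroundModel,
    p_cutoff: float = 0.001,
    tol: float = 1e-6,
) -> float:
    """Smallest corrected density whose tail probability drops below p_cutoff.

    Bisection on [min(samples) - 10h, max(samples) + 10h]; valid because
    the tail probability is monotone non-increasing in x.
    """
    if not (0.0 < p_cutoff < 1.0):
        raise ValueError(f"p_cutoff must be in (0, 1), got {p_cutoff}")
    lo = float(model.samples.min()) - 10.0 * model.h
    hi = float(model.samples.max()) + 10.0 * model.h
    if tail_probability(model, lo) < p_cutoff:
        return lo
    # tail(hi) <= n Gaussian tails at 10 sigma << any sensible cutoff
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if tail_probability(model, mid) < p_cutoff:
            hi = mid
        else:
            lo = mid
    return hi
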