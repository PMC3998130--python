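# Methods

## Signal statistic

`kdepeaks` treats each mapped read as a single point: its strand-aware
start site (BED start on `+` and on strandless reads; BED end − 1 on
`-`), because in DNaseI-seq the 5' end of a read approximates a DNaseI
cut site and cut density — not read coverage — marks open chromatin.
An optional offset shifts every start toward 3' on its own strand, which
lets the same statistic serve ChIP-seq or FAIRE-seq data whose
informative position sits inside the fragment. All coordinates are
0-based half-open.

Signal at a locus is the corrected read density of a nested dual bin
centred there: the read-start count in a central bin of `c` bp minus
the count expected from the surrounding background bin of `b` bp,

    d = n_c − n_b · (c / b).

Defaults are c = 300 and b = 3000; a bin of width `w` centred at `x`
spans `[x − w//2, x − w//2 + w)` so both bins share their midpoint
exactly. The subtraction makes the statistic local: a site inside a
broad high-coverage domain is judged against that domain, not against
the genome average. `d` can be negative (central bin emptier than its
surroundings); negative values are deliberately retained in the
background sample, since truncating them would bias the left flank of
the estimated null and inflate the threshold.

## Background model and threshold

The null distribution of `d` is estimated per dataset. `n_sites`
(default 50 000) centres are drawn uniformly over all valid placements
(background bin fully inside a chromosome; chromosomes weighted by
their valid-centre count), and a single pass in draw order discards any
site whose background bin overlaps an earlier retained site. No
replacement draws are made, so small genomes yield fewer retained
sites — at most about `genome_size / b` — and the model requires at
least 2. Sites near chromosome edges are excluded from the sampling
universe rather than truncated, keeping the expected-count arithmetic
exact; chromosomes shorter than the background bin are skipped with a
logged notice.

The retained corrected densities `x_i` are smoothed by a Gaussian KDE
with fixed bandwidth `h = 1` (in units of reads per central bin):

    f(x) = (1 / n h) Σᵢ K((x − x_i)/h),  K the standard normal pdf.

The bandwidth is a model constant, not auto-selected: the statistic is
count-like with unit granularity, so `h = 1` smooths between adjacent
integer values without washing out the distribution's shape. It can be
overridden (`--bandwidth`) but there is no Silverman or cross-validation
machinery by design.

"How surprising is density `x`?" is answered by the upper-tail mass
`P(X ≥ x) = (1/n) Σᵢ Φ((x_i − x)/h)`, computed in closed form from the
normal survival function (density height would carry units and no
[0, 1] scale, so a fixed cutoff on it would depend on bin geometry).
The calling threshold is the smallest `x` with `P(X ≥ x) < p_cutoff`
(default 0.001), found by bisection on
`[min(x_i) − 10h, max(x_i) + 10h]` to a 1e-6 tolerance — valid because
the tail mass is monotone non-increasing. All randomness flows from a
single user seed, and a fixed seed makes the whole model, threshold
included, bit-reproducible.

## Genome scan and peak formation

Each chromosome is tiled with dual bins whose centres run from `b/2` to
`chrom_length − b/2` in steps of 100 bp (a third of the central bin, so
every base falls under at least three central windows; any step up to
the central size is accepted, larger steps are rejected because the
scan bins must overlap). Counting uses `searchsorted` on the sorted
start positions, so a chromosome scan is a handful of vectorised array
operations. Bins with `d` strictly above the threshold are flagged and
annotated with their tail probability.

Maximal runs of flagged bins whose central windows overlap or abut
exactly are merged into one peak; a gap of one or more bp splits peaks.
Peak extent is the union of the run's central windows — the measured
signal footprint, not the background windows. Peaks are scored by the
run's maximum corrected density and minimum tail probability; the
summit is the centre of the maximal bin, leftmost on ties for
determinism. BED output carries either the density score or
`−log10(min tail probability)`.

## Synthetic data

The generator emulates the rate structure a peak caller must resolve:
background read starts are a homogeneous Poisson process
(`background_rate` reads/bp, default 0.01 in the CLI — about 0.3 reads
per central bin, a sparse, low-SNR regime), and each spiked region adds
an independent Poisson component at `(enrichment − 1) × rate`, so the
region's total rate is `enrichment × rate` and the expected corrected
density of a covered central bin is analytically
`(enrichment − 1) × rate × c`. Strand is a fair coin independent of
position; reads have fixed length (default 36 bp) and reads that would
cross a chromosome edge are dropped.

Deliberately not modelled: DNaseI sequence cut bias, mappability,
GC bias, duplicate reads, and fragment-length variation. Passing tests
therefore demonstrate that the algorithm recovers rate-defined
enrichment over Poisson noise — they do not certify performance against
real-data artefacts such as mappability holes or PCR duplicate towers.

## Behaviour at small genome sizes

Two coupled effects matter when the pipeline runs on megabase-scale
simulations rather than a full genome. First, overlap discarding caps
retained background sites near `genome_size / b` (≈ 2 400 on 10 Mb, 333
on 1 Mb), far below the 50 000 the sampler draws. Second, each retained
sample carries tail weight `1/n`, so when `p_cutoff < 1/n` the
threshold necessarily lands beyond the largest sample, and any
background site that happened to fall on a genuinely enriched region
drags the threshold up toward the contamination's own density. On a
full-size genome with 50 000 retained sites this contamination is
negligible (each sample weighs 2×10⁻⁵); on a 10-Mb simulation a
handful of contaminated samples can shift the threshold enough to miss
the weakest spiked regions in some replicates. The recovery test
therefore asserts the average over five seeded replicates. Users
simulating small genomes should read thresholds with this in mind or
lower `n_sites` expectations accordingly.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `central_size` | 300 | bp | signal footprint; roughly nucleosome-free region scale |
| `background_size` | 3000 | bp | local-background context; must exceed central |
| `n_sites` | 50 000 | sites | drawn before overlap discarding |
| `bandwidth` (`h`) | 1 | reads/central bin | fixed KDE smoothing |
| `p_cutoff` | 0.001 | probability | tail mass at the threshold |
| `step` | 100 | bp | scan stride; must be ≤ central size |
| `offset` | 0 | bp | 3'-ward start shift for ChIP-/FAIRE-seq reuse |
| `seed` | 20131204 | — | sole entropy source |

## Numerical choices and edge cases

- Gaussian pdf/survival values come from `scipy.special` closed forms;
  numerical integration appears only as an independent oracle in tests.
- Threshold bisection tolerance is 1e-6 in density units; reported
  thresholds are exact for the retained sample set.
- Bins are half-open everywhere; a read start exactly at a window end
  is outside it.
- Empty read files, read-free chromosomes and empty peak lists are
  valid inputs/outputs, not errors; malformed BED lines fail fast with
  the line number.
- Reads whose (shifted) start leaves the chromosome are dropped and
  counted in the log, never clamped.
- Peak output refuses overlapping or unsorted peaks; merging is the
  scanner's job and the writer only serialises.

## Limitations

- No FDR or q-value across peaks: thresholding is one global cutoff per
  dataset, by construction.
- No control-sample (input/IgG) handling and no replicate merging.
- BED input only; convert BAM upstream (`bedtools bamtobed`).
- The background sampler assumes reads are sparse relative to the
  genome; datasets where enriched regions occupy a large genome
  fraction will contaminate the null and raise the threshold (see the
  small-genome discussion above, which is the same effect).
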