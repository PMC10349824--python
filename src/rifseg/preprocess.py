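"""Preprocessing of normalized coverage/probe input into filtered bin series.

The pipeline operates on *bins*: fixed-width (default 50 nt) windows of
per-nucleotide coverage, addressed by the 1-based genome coordinate of the
last nucleotide in the bin, with an abundance matrix over replicates and
time points.  Preprocessing consists of

1. binning per-nucleotide coverage (:func:`bin_coverage`),
2. discarding low-count bins and, for microarrays, implausible probes
   (:func:`filter_low`),
3. splitting the genome into independent coverage segments at expression
   gaps (:func:`split_by_gaps`) so the polynomial-time segmentation runs
   on small pieces,
4. tagging microarray probes for the constant-background model
   (:func:`tag_bg_model`),
5. flagging candidate rifampicin-sensitive-termination (RST) regions via
   an indicator-sequence segmentation (:func:`flag_rst_candidates`).

Coordinates are 1-based and inclusive throughout; "upstream" means
smaller coordinates on the + strand and larger coordinates on the -
strand.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from rifseg import segmentation as _seg

__all__ = [
    "BinSeries",
    "bin_coverage",
    "filter_low",
    "split_by_gaps",
    "tag_bg_model",
    "flag_rst_candidates",
]


@dataclass
class BinSeries:
    """One genomic bin (or microarray probe) with its abundance time series.

    ``abundance`` has shape ``(n_replicates, n_times)``; ``times`` are the
    sampling times in minutes, sorted ascending and starting at 0.
    ``position`` is the 1-based coordinate of the last nucleotide in the
    bin.
    """

    position: int
    strand: str
    abundance: np.ndarray
    times: np.ndarray
    width: int = 50
    filtered: bool = False
    bg_model: bool = False
    rst_candidate: bool = False
    segment_id: int | None = None

    def __post_init__(self) -> None:
        self.abundance = np.atleast_2d(np.asarray(self.abundance, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.abundance.shape[1] != self.times.size:
            raise ValueError("abundance matrix and time grid disagree")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly ascending")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def mean_series(self) -> np.ndarray:
        """Across-replicate mean abundance at each time point."""
        return self.abundance.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.abundance.mean())


def bin_coverage(coverage: np.ndarray, times, strand: str = "+",
                 bin_width: int = 50) -> list[BinSeries]:
    """Average per-nucleotide coverage into fixed-width bins.

    Parameters
    ----------
    coverage : ndarray, shape (n_replicates, n_times, genome_length)
        Normalized per-nucleotide coverage for one strand; index 0 of the
        last axis is nucleotide 1.
    times : array-like
        Sampling times in minutes.
    bin_width : int
        Bin width in nt; a ragged final bin is averaged over its actual
        width and retained.
    """
    coverage = np.asarray(coverage, dtype=float)
    if coverage.ndim != 3:
        raise ValueError("coverage must have shape (replicates, times, genome length)")
    glen = coverage.shape[2]
    bins: list[BinSeries] = []
    for start in range(0, glen, bin_width):
        stop = min(start + bin_width, glen)
        vals = coverage[:, :, start:stop].mean(axis=2)
        bins.append(BinSeries(position=stop, strand=strand, abundance=vals,
                              times=times, width=stop - start))
    return bins


def filter_low(bins: list[BinSeries], min_mean: float = 10.0,
               platform: str = "rnaseq") -> list[BinSeries]:
    """Drop bins whose grand mean over all replicates and time points is
    below ``min_mean``.

    In microarray mode, probes whose (mean) expression peaks at the last
    time point or bottoms out at the first time point are additionally
    removed — both shapes are incompatible with any decay model.
    """
    kept = []
    for b in bins:
        if b.grand_mean < min_mean:
            continue
        if platform == "microarray":
            m = b.mean_series
            if int(np.argmax(m)) == m.size - 1 or int(np.argmin(m)) == 0:
                continue
        kept.append(b)
    return kept


def split_by_gaps(bins: list[BinSeries], max_gap: float = 300.0) -> list[BinSeries]:
    """Assign coverage-segment ids: consecutive bins on the same strand
    whose positional spacing exceeds ``max_gap`` nt start a new segment.

    Returns the bins sorted by (strand, position) with ``segment_id`` set.
    """
    out = sorted(bins, key=lambda b: (b.strand, b.position))
    seg = -1
    prev: BinSeries | None = None
    for b in out:
        if prev is None or b.strand != prev.strand or (b.position - prev.position) > max_gap:
            seg += 1
        b.segment_id = seg
        prev = b
    return out


def tag_bg_model(bins: list[BinSeries], bg_threshold: float = 4000.0,
                 platform: str = "microarray") -> list[BinSeries]:
    """Tag probes for the constant-background model variant.

    Microarray probes whose mean abundance at the last time point lies
    below ``bg_threshold`` (arbitrary units) still contain signal over the
    array background and are fitted with the background model; probes
    above it, and all RNA-seq bins, use the plain model.
    """
    for b in bins:
        b.bg_model = bool(platform == "microarray" and b.mean_series[-1] < bg_threshold)
    return bins


def rst_indicator(b: BinSeries, increase_threshold: float = 0.075) -> int:
    """+1 if any post-rifampicin time point of the replicate-mean series
    exceeds the t=0 value by more than ``increase_threshold`` (relative),
    else -1."""
    m = b.mean_series
    if m[0] <= 0:
        return -1
    return 1 if np.any(m[1:] > m[0] * (1.0 + increase_threshold)) else -1


def flag_rst_candidates(bins: list[BinSeries], increase_threshold: float = 0.075,
                        penalty: float = 10.0, min_frac: float = 0.75,
                        upstream_extension: float = 1000.0) -> list[BinSeries]:
    """Flag bins in candidate RST regions for fitting with the RST model.

    Each bin gets an indicator y in {-1, +1} marking a >7.5% relative
    abundance rise after rifampicin.  Per coverage segment the indicator
    sequence is segmented by the exact DP with the
    absolute-deviation-from-mean score and the given split penalty;
    segments with at least ``min_frac`` of +1 bins are flagged, together
    with the bins covering ``upstream_extension`` nt 5' of each flagged
    segment (strand-aware) so that the pre-RST phase is fitted with the
    same model.
    """
    if not bins:
        return bins
    if any(b.segment_id is None for b in bins):
        bins = split_by_gaps(bins)
    by_seg: dict[int, list[BinSeries]] = {}
    for b in bins:
        b.rst_candidate = False
        by_seg.setdefault(b.segment_id, []).append(b)
    for seg_bins in by_seg.values():
        seg_bins.sort(key=lambda b: b.position)
        y = np.array([rst_indicator(b, increase_threshold) for b in seg_bins], dtype=float)
        frags = _seg.dp_segment(y, _seg.indicator_scorer(), penalty=penalty, min_len=1)
        flagged_ranges = []
        for fr in frags:
            member = y[fr.start:fr.stop]
            if np.mean(member == 1.0) >= min_frac:
                for b in seg_bins[fr.start:fr.stop]:
                    b.rst_candidate = True
                flagged_ranges.append((seg_bins[fr.start].position, seg_bins[fr.stop - 1].position))
        # extend upstream of each flagged run so the pre-RST phase is co-fitted
        for lo, hi in flagged_ranges:
            strand = seg_bins[0].strand
            for b in seg_bins:
                if strand == "+" and lo - upstream_extension <= b.position < lo:
                    b.rst_candidate = True
                elif strand == "-" and hi < b.position <= hi + upstream_extension:
                    b.rst_candidate = True
    return bins
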