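"""Canonical k-mer histograms and coverage-peak genome-size estimation.

The estimator is the transparent peak-ratio rule used in k-mer genome
surveys: count canonical k-mers (a k-mer and its reverse complement are one
key), histogram the per-k-mer depths, locate the error valley and the
coverage peak, and divide the retained k-mer instance total by the peak
depth. It deliberately stops short of the negative-binomial mixture fit of
GenomeScope-class tools; heterozygosity and repeat fractions are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.signal import find_peaks

from .contigs import ContigSet
from .exceptions import EstimationError, InputError

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("N")] = 4

# Peaks smaller than this fraction of the largest smoothed count are treated
# as shot noise when classifying the histogram as uni- vs multi-modal.
PEAK_PROMINENCE_FRACTION = 0.025


@dataclass(frozen=True)
class KmerHistogram:
    """Depth histogram of distinct canonical k-mers.

    ``counts[d]`` is the number of distinct canonical k-mers observed at
    depth ``d``; the sum of ``d * counts[d]`` equals the total number of
    k-mer instances counted.
    """

    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise InputError("k must be odd and >= 3")
        if any(d < 1 for d in self.counts):
            raise InputError("histogram depths must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise InputError("histogram counts must be >= 0")

    @property
    def total_instances(self) -> int:
        return sum(d * c for d, c in self.counts.items())

    @property
    def total_distinct(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        """Write the two-column ``depth<TAB>count`` histogram dialect."""
        with open(path, "w") as fh:
            for d in sorted(self.counts):
                fh.write(f"{d}\t{self.counts[d]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int) -> "KmerHistogram":
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                d, c = line.split()
                counts[int(d)] = int(c)
        return cls(k=k, counts=counts)


def count_kmers(
    reads: ContigSet | Iterable[str], k: int, max_depth: int = 10_000
) -> KmerHistogram:
    """Count canonical k-mers across reads and histogram their depths.

    Canonical key = lexicographic minimum of a k-mer and its reverse
    complement (with A<C<G<T, equivalently the smaller 2-bit packed code).
    Windows containing N are skipped. Depths above ``max_depth`` are
    accumulated into an overflow bin at ``max_depth``. k is capped at 31 so
    packed codes fit in 64 bits — ample for desk-scale genomes.
    """
    if k % 2 == 0:
        raise InputError("k must be odd (even k makes canonicalization ambiguous)")
    if k < 3:
        raise InputError("k must be >= 3")
    if k > 31:
        raise InputError("k must be <= 31 for 2-bit packed counting")

    seqs = reads.sequences() if isinstance(reads, ContigSet) else list(reads)
    # concatenate with sentinel separators so one vectorized pass suffices
    blob = b"N".join(s.upper().encode("ascii") for s in seqs)
    arr = _ENCODE[np.frombuffer(blob, dtype=np.uint8)]
    if (arr == 255).any():
        raise InputError("reads must be over {A,C,G,T,N}")
    m = len(arr) - k + 1
    if m < 1:
        return KmerHistogram(k=k, counts={})

    a64 = arr.astype(np.uint64)
    comp = (np.uint64(3) - a64) & np.uint64(3)  # complement; junk where N, masked below
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | a64[j : j + m]
        rev = (rev << np.uint64(2)) | comp[k - 1 - j : k - 1 - j + m]

    bad = (arr >= 4).astype(np.int64)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0

    canon = np.minimum(fwd[valid], rev[valid])
    if canon.size == 0:
        return KmerHistogram(k=k, counts={})
    _, depth = np.unique(canon, return_counts=True)
    depth = np.minimum(depth, max_depth)
    hist = np.bincount(depth)
    counts = {int(d): int(c) for d, c in enumerate(hist) if d >= 1 and c > 0}
    return KmerHistogram(k=k, counts=counts)


@dataclass(frozen=True)
class GenomeSizeEstimate:
    peak_depth: int
    error_valley_depth: int
    estimated_size_bp: int
    n_peaks_detected: int
    homozygosity_call: str  # "homozygous-like" | "heterozygous-like"

    def format_line(self) -> str:
        return (
            f"Peak k-mer depth {self.peak_depth}, estimated haploid genome "
            f"length {self.estimated_size_bp:,} bp "
            f"({self.n_peaks_detected} peak(s): {self.homozygosity_call})"
        )


def _smooth(dense: np.ndarray, window: int) -> np.ndarray:
    if len(dense) < window:
        return dense.astype(float).copy()
    kernel = np.ones(window)
    return np.convolve(dense, kernel, mode="same") / np.convolve(
        np.ones_like(dense), kernel, mode="same"
    )


def estimate_genome_size(
    hist: KmerHistogram, smooth_window: int = 3
) -> GenomeSizeEstimate:
    """Estimate haploid genome size from a k-mer depth histogram.

    The error valley is the first local minimum of the (moving-average
    smoothed) counts-vs-depth curve; depths below it are attributed to
    sequencing errors and excluded. The coverage peak is the argmax of the
    smoothed counts from the valley on, and the size estimate is
    ``round(sum_{d >= valley} d * counts[d] / peak_depth)``. A histogram that
    only decreases — error k-mers with no coverage peak — raises
    :class:`EstimationError`. Peak multiplicity (after smoothing, ignoring
    bumps below a small prominence floor) drives the homozygosity call: a
    single peak is "homozygous-like", more are "heterozygous-like".
    """
    if not hist.counts:
        raise InputError("histogram is empty")
    depths = np.array(sorted(hist.counts))
    vals = np.array([hist.counts[d] for d in depths], dtype=float)
    # Smooth along the occupied-depth grid: invariant to uniform depth
    # rescaling (e.g. duplicating the read set), and identical to dense
    # smoothing for the contiguous histograms real surveys produce.
    grid_s = _smooth(vals, smooth_window)

    if len(depths) == 1 or depths[0] > 2 or grid_s[0] <= grid_s[1]:
        # no error component: single depth, support starting well above the
        # depth-1..2 regime error k-mers occupy, or counts rising from the start
        valley_pos = 0
        valley = 0
    else:
        for i in range(1, len(depths) - 1):
            if grid_s[i] <= grid_s[i + 1]:
                valley_pos = i
                valley = int(depths[i])
                break
        else:
            raise EstimationError(
                "histogram decreases monotonically with depth: only the "
                "error peak is present, no coverage peak to estimate from "
                f"(support {depths[0]}..{depths[-1]})"
            )

    peak_depth = int(depths[valley_pos + int(np.argmax(grid_s[valley_pos:]))])

    # Peak counting uses the dense depth axis so well-separated modes stay
    # distinct even when the occupied depths are sparse.
    d_max = int(depths[-1])
    dense = np.zeros(d_max, dtype=float)
    dense[depths - 1] = vals
    start = max(valley, 1)
    region = _smooth(dense, smooth_window)[start - 1 :]
    padded = np.concatenate([[0.0], region, [0.0]])
    peaks, _ = find_peaks(
        padded, prominence=PEAK_PROMINENCE_FRACTION * padded.max()
    )
    n_peaks = max(1, len(peaks))

    retained = sum(d * c for d, c in hist.counts.items() if d >= start)
    size = int(round(retained / peak_depth))
    return GenomeSizeEstimate(
        peak_depth=peak_depth,
        error_valley_depth=valley,
        estimated_size_bp=size,
        n_peaks_detected=n_peaks,
        homozygosity_call="homozygous-like" if n_peaks == 1 else "heterozygous-like",
    )
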