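"""Genome signal-track operations.

Percentile-threshold peak calling on binned coverage tracks, replicate
consensus, classification of cohesin-subunit binding relative to R-loop
peaks (overlap / adjacent within a gap / distal), mean signal profiles
around regions, and treatment-induced percent signal change. All intervals
are 0-based half-open; strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 when overlapping or touching."""
        if self.chrom != other.chrom:
            raise ValueError("gap between different chromosomes")
        return max(0, self.start - other.end, other.start - self.end)


@dataclass
class SignalTrack:
    """Per-bin signal on one chromosome (bins of ``bin_size`` bp from 0)."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("track values must be finite and non-negative")


def call_peaks_percentile(track: SignalTrack, q: float = 0.995) -> list[GenomicInterval]:
    """Peaks = maximal runs of bins strictly above the empirical q-quantile
    (linear-interpolation quantile) of the per-bin values.

    The strict inequality means a constant (or q-quantile-saturated) track
    yields no peaks rather than calling the whole chromosome.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    threshold = np.quantile(track.values, q)
    above = track.values > threshold
    peaks = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        peaks.append(
            GenomicInterval(track.chrom, run_start * track.bin_size,
                            run_end * track.bin_size)
        )
    return peaks


def replicate_consensus(
    peaks_r1: list[GenomicInterval], peaks_r2: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Replicate 1 peaks with >= 1 bp overlap against any replicate 2 peak
    (replicate 1 coordinates are kept)."""
    return [p for p in peaks_r1 if any(p.overlaps(r) for r in peaks_r2)]


def classify_relative_position(
    sa_peaks: list[GenomicInterval],
    rloop_peaks: list[GenomicInterval],
    adjacency: int = 2000,
) -> list[str]:
    """Label each R-loop peak: ``overlap`` if any SA peak shares >= 1 bp,
    else ``adjacent`` if the nearest SA peak lies within ``adjacency`` bp
    edge-to-edge, else ``distal``."""
    labels = []
    for rloop in rloop_peaks:
        same_chrom = [p for p in sa_peaks if p.chrom == rloop.chrom]
        if any(rloop.overlaps(p) for p in same_chrom):
            labels.append("overlap")
        elif same_chrom and min(rloop.gap_to(p) for p in same_chrom) <= adjacency:
            labels.append("adjacent")
        else:
            labels.append("distal")
    return labels


def _region_profile_row(track: SignalTrack, region: GenomicInterval,
                        flank: int, n_bins: int) -> np.ndarray:
    """One region's profile: the region expanded by ``flank`` on both sides,
    resampled to ``n_bins``; positions off the track contribute zero."""
    start = region.start - flank
    end = region.end + flank
    centers = start + (np.arange(n_bins) + 0.5) * (end - start) / n_bins
    idx = np.floor(centers / track.bin_size).astype(int)
    row = np.zeros(n_bins)
    valid = (idx >= 0) & (idx < len(track.values))
    row[valid] = track.values[idx[valid]]
    return row


def mean_profile(track: SignalTrack, regions: list[GenomicInterval],
                 flank: int = 2000, n_bins: int = 100) -> np.ndarray:
    """Per-bin mean signal across regions, each expanded by ``flank`` bp
    up- and downstream; missing data (off-track positions) is treated as
    zero."""
    if not regions:
        raise ValueError("regions must be non-empty")
    rows = [_region_profile_row(track, r, flank, n_bins) for r in regions]
    return np.mean(rows, axis=0)


def _region_bin_mask(track: SignalTrack, regions: list[GenomicInterval]) -> np.ndarray:
    mask = np.zeros(len(track.values), dtype=bool)
    for r in regions:
        if r.chrom != track.chrom:
            continue
        lo = r.start // track.bin_size
        hi = -(-r.end // track.bin_size)
        mask[max(lo, 0) : min(hi, len(mask))] = True
    return mask


def percent_signal_change(track_control: SignalTrack, track_treated: SignalTrack,
                          regions: list[GenomicInterval]) -> float:
    """100 * (mean_treated - mean_control) / mean_control, means over
    region-covered bins."""
    if track_control.bin_size != track_treated.bin_size:
        raise ValueError("tracks must share a bin size")
    if len(track_control.values) != len(track_treated.values):
        raise ValueError("tracks must share a binning")
    mask = _region_bin_mask(track_control, regions)
    if not mask.any():
        raise ValueError("regions cover no track bins")
    mean_c = float(track_control.values[mask].mean())
    mean_t = float(track_treated.values[mask].mean())
    if mean_c == 0:
        raise ValueError("control mean is zero over the regions")
    return 100.0 * (mean_t - mean_c) / mean_c


def rnh_sensitive_sites(track_control: SignalTrack, track_treated: SignalTrack,
                        peaks: list[GenomicInterval], tau: float = 0.5,
                        ) -> list[GenomicInterval]:
    """Peaks whose mean signal drops by a fraction >= ``tau`` under
    treatment (e.g. RNase H), the selection rule for treatment-sensitive
    R-loop sites."""
    kept = []
    for peak in peaks:
        mask = _region_bin_mask(track_control, [peak])
        if not mask.any():
            continue
        mean_c = track_control.values[mask].mean()
        mean_t = track_treated.values[mask].mean()
        if mean_c > 0 and (mean_c - mean_t) / mean_c >= tau:
            kept.append(peak)
    return kept
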