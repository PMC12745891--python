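"""Respiratory binning: amplitude-based (4D-MR style) and phase-based (4D-CT style).

Amplitude binning slices the surrogate amplitude range into equal-width bands
and mixes inhalation and exhalation samples of equal amplitude (hysteresis is
ignored, as in the vendor reconstruction). Phase binning assigns each sample a
fractional position within its breathing cycle, measured between consecutive
end-inhale peaks, with bin 0 centered on the peak so that the extreme bins of
both modes are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateTraceError, NoCyclesError
from .waveforms import RespiratoryTrace, detect_cycles

#: Robust amplitude range for bin edges, percentiles of the trace amplitude.
#: Keeps transient sharp inhales from compressing regular breathing into a
#: few low bins.
ROBUST_RANGE_PERCENTILES = (1.0, 99.0)


@dataclass(frozen=True)
class BinAssignment:
    """Per-sample respiratory bin indices plus bin-edge metadata.

    ``edges`` are amplitude boundaries in mm for amplitude mode and phase
    fractions in [0, 1) for phase mode (bin 0 straddles phase 0, the
    end-inhale peak). In amplitude mode bin 0 is end-exhale (lowest
    amplitudes) and bin ``n_bins - 1`` end-inhale.
    """

    n_bins: int
    mode: str  # "amplitude" | "phase"
    edges: np.ndarray
    bin_index: np.ndarray
    t: np.ndarray
    a: np.ndarray

    def __post_init__(self):
        if self.mode not in ("amplitude", "phase"):
            raise ValueError("mode must be 'amplitude' or 'phase'")
        if self.bin_index.min(initial=0) < 0 or self.bin_index.max(initial=0) >= self.n_bins:
            raise ValueError("bin_index out of range")

    @property
    def occupancy(self) -> np.ndarray:
        """Sample count per bin; sums to the number of samples."""
        return np.bincount(self.bin_index, minlength=self.n_bins)

    def centroids(self) -> np.ndarray:
        """Mean amplitude of the samples in each bin (NaN for empty bins)."""
        out = np.full(self.n_bins, np.nan)
        for b in range(self.n_bins):
            sel = self.bin_index == b
            if sel.any():
                out[b] = self.a[sel].mean()
        return out

    def medians(self) -> np.ndarray:
        """Median amplitude of the samples in each bin (NaN for empty bins)."""
        out = np.full(self.n_bins, np.nan)
        for b in range(self.n_bins):
            sel = self.bin_index == b
            if sel.any():
                out[b] = np.median(self.a[sel])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_index": np.arange(len(self.bin_index)),
                "time_s": self.t,
                "amp_mm": self.a,
                "bin_index": self.bin_index,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _amplitude_edges(a: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = np.percentile(a, ROBUST_RANGE_PERCENTILES)
    if hi - lo <= 0:
        raise DegenerateTraceError("constant trace cannot be amplitude-binned into > 1 bin")
    return np.linspace(lo, hi, n_bins + 1)


def assign_amplitudes(amps: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin arbitrary amplitudes with existing edges; outliers clamp to the
    extreme bins (the vendor sorts every acquired view somewhere)."""
    n_bins = len(edges) - 1
    return np.clip(np.digitize(amps, edges[1:-1]), 0, n_bins - 1).astype(int)


def amplitude_bins(trace: RespiratoryTrace, n_bins: int) -> BinAssignment:
    """Equal-width amplitude bins over the robust (1st-99th pct) range.

    Inhale and exhale samples of equal amplitude land in the same bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins == 1:
        edges = np.array([trace.a.min(), trace.a.max()])
        idx = np.zeros(len(trace.a), dtype=int)
    else:
        edges = _amplitude_edges(trace.a, n_bins)
        idx = assign_amplitudes(trace.a, edges)
    return BinAssignment(n_bins, "amplitude", edges, idx, trace.t, trace.a)


def phase_fractions(trace: RespiratoryTrace) -> np.ndarray:
    """Per-sample phase in [0, 1): elapsed fraction between consecutive
    end-inhale peaks (0 at the peak, 0.5 near the trough).

    Samples before the first / after the last detected peak are extrapolated
    with the adjacent cycle's period.
    """
    cycles = detect_cycles(trace)
    peaks = cycles.peak_indices
    if len(peaks) < 2:
        raise NoCyclesError("phase binning needs at least one complete peak-to-peak cycle")
    tp = trace.t[peaks]
    phase = np.empty(len(trace.t))
    # in-cycle samples
    seg = np.searchsorted(tp, trace.t, side="right") - 1
    inside = (seg >= 0) & (seg < len(tp) - 1)
    s = seg[inside]
    phase[inside] = (trace.t[inside] - tp[s]) / (tp[s + 1] - tp[s])
    # extrapolate leading / trailing partial cycles
    first_T = tp[1] - tp[0]
    last_T = tp[-1] - tp[-2]
    before = trace.t < tp[0]
    after = trace.t >= tp[-1]
    phase[before] = np.mod((trace.t[before] - tp[0]) / first_T, 1.0)
    phase[after] = np.mod((trace.t[after] - tp[-1]) / last_T, 1.0)
    return np.mod(phase, 1.0)


def phase_bins(trace: RespiratoryTrace, n_phases: int) -> BinAssignment:
    """Phase-based bins; bin k covers phase [k/n - 1/(2n), k/n + 1/(2n)),
    so bin 0 is centered on the end-inhale peak."""
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    phase = phase_fractions(trace)
    idx = np.floor(np.mod(phase + 0.5 / n_phases, 1.0) * n_phases).astype(int)
    idx = np.clip(idx, 0, n_phases - 1)
    edges = np.mod(np.arange(n_phases) / n_phases - 0.5 / n_phases, 1.0)
    return BinAssignment(n_phases, "phase", edges, idx, trace.t, trace.a)


def extreme_bins(assign: BinAssignment) -> tuple[int, int]:
    """(end-exhale bin, end-inhale bin): the two bins the displacement
    measurement compares."""
    n = assign.n_bins
    if n < 2:
        raise ValueError("extreme bins undefined for a single bin")
    if assign.mode == "amplitude":
        return 0, n - 1
    trough_bin = int(np.floor((0.5 + 0.5 / n) * n)) % n
    return trough_bin, 0
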