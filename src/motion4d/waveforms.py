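"""Respiratory surrogate waveforms.

Generates, reads, scales and classifies the breathing traces that drive the
moving-sphere phantom: ideal sinusoids (programmed peak-to-peak displacement
``pp_mm`` and period ``period_s``) and patient-like traces in three regularity
classes (regular / semiregular / irregular).

Amplitude scaling uses the mean of the per-cycle maximum excursions rather
than the global maximum, so that transient sharp inhales in irregular traces
do not compress the bulk of the breathing cycle into a small motion range.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateTraceError, NoCyclesError, TraceParseError

CATEGORIES = ("regular", "semiregular", "irregular", "sinusoid", "unknown")

#: Peak prominence as a fraction of the global peak-to-peak excursion.
PEAK_PROMINENCE_FRACTION = 0.20
#: Minimum separation between breathing peaks, seconds.
MIN_PEAK_SEPARATION_S = 1.0


@dataclass(frozen=True)
class RespiratoryTrace:
    """Uniformly sampled surrogate amplitude vs time.

    ``a`` is the displacement of the phantom insert along the motion axis in
    mm; ``t`` in seconds with uniform spacing ``dt``.
    """

    t: np.ndarray
    a: np.ndarray
    dt: float
    label: str = ""
    category: str = "unknown"

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "a", a)
        if t.ndim != 1 or a.ndim != 1 or len(t) != len(a) or len(t) < 2:
            raise ValueError("t and a must be equal-length 1-D arrays with >= 2 samples")
        d = np.diff(t)
        if np.any(d <= 0):
            raise ValueError("t must be strictly increasing")
        if np.max(np.abs(d - self.dt)) > 1e-9:
            raise ValueError("t must be uniformly spaced within 1e-9 s")
        if not np.all(np.isfinite(a)):
            raise ValueError("amplitudes must be finite")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def pp(self) -> float:
        """Global peak-to-peak excursion, mm."""
        return float(self.a.max() - self.a.min())

    def amplitude_at(self, times: np.ndarray) -> np.ndarray:
        """Amplitude at arbitrary times, looping the trace end-to-start.

        Traces shorter than an acquisition are repeated until the acquisition
        completes, mirroring how the phantom software replays its input.
        """
        times = np.asarray(times, dtype=float)
        span = self.duration + self.dt  # loop period includes one dt gap
        wrapped = self.t[0] + np.mod(times - self.t[0], span)
        return np.interp(wrapped, self.t, self.a)


@dataclass(frozen=True)
class CycleSet:
    """Per-cycle extrema of a trace.

    ``cycle_pp`` holds each cycle's peak-to-trough excursion in mm (the
    per-cycle "maximum amplitude" used for phantom programming).
    """

    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    trough_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cycle_pp: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    @property
    def n_cycles(self) -> int:
        return len(self.peak_indices)


def generate_sinusoid(
    pp_mm: float,
    period_s: float,
    duration_s: float,
    dt: float = 0.01,
    phase: float = 0.0,
) -> RespiratoryTrace:
    """Zero-mean sinusoid with peak-to-peak excursion ``pp_mm``.

    The programmed "displacement" of the phantom is peak-to-peak: a 10 mm
    waveform moves the sphere 5 mm either side of rest.
    """
    if period_s <= 0 or dt <= 0:
        raise ValueError("period_s and dt must be positive")
    if pp_mm < 0:
        raise ValueError("pp_mm must be non-negative")
    if duration_s < period_s:
        raise ValueError("duration_s must cover at least one period")
    if dt >= period_s / 10:
        raise ValueError("dt must resolve the period (dt < period_s / 10)")
    n = int(round(duration_s / dt)) + 1
    t = np.arange(n) * dt
    a = (pp_mm / 2.0) * np.sin(2 * np.pi * t / period_s + phase)
    return RespiratoryTrace(t, a, dt, label=f"sin_pp{pp_mm:g}_T{period_s:g}", category="sinusoid")


def _alternating_extrema(a: np.ndarray, peaks: np.ndarray, troughs: np.ndarray):
    """Merge peak/trough candidates into a strictly alternating sequence.

    Runs of consecutive same-type extrema keep only the most extreme member.
    """
    events = [(i, +1) for i in peaks] + [(i, -1) for i in troughs]
    events.sort()
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = a[idx] > a[prev] if kind > 0 else a[idx] < a[prev]
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    p = np.array([i for i, k in kept if k > 0], dtype=int)
    q = np.array([i for i, k in kept if k < 0], dtype=int)
    return p, q


def detect_cycles(trace: RespiratoryTrace) -> CycleSet:
    """Segment a trace into breathing cycles via prominence-based peak finding.

    A constant trace yields an empty :class:`CycleSet`. The prominence
    threshold (20% of global excursion) rejects cardiac-scale ripple while the
    1 s minimum separation keeps 2.4 s breathing resolvable.
    """
    if len(trace.a) < 3:
        raise ValueError("trace must have at least 3 samples")
    pp = trace.pp
    if pp <= 0:
        return CycleSet()
    distance = max(1, int(round(MIN_PEAK_SEPARATION_S / trace.dt)))
    prom = PEAK_PROMINENCE_FRACTION * pp
    peaks, _ = find_peaks(trace.a, prominence=prom, distance=distance)
    troughs, _ = find_peaks(-trace.a, prominence=prom, distance=distance)
    peaks, troughs = _alternating_extrema(trace.a, peaks, troughs)
    if len(peaks) == 0:
        return CycleSet(trough_indices=troughs)
    cycle_pp = np.empty(len(peaks))
    for j, p in enumerate(peaks):
        before = troughs[troughs < p]
        after = troughs[troughs > p]
        vals = []
        if len(before):
            vals.append(trace.a[before[-1]])
        if len(after):
            vals.append(trace.a[after[0]])
        if not vals:  # no trough detected at all; fall back to global minimum
            vals.append(float(trace.a.min()))
        cycle_pp[j] = trace.a[p] - float(np.mean(vals))
    return CycleSet(peaks, troughs, cycle_pp)


def mean_max_amplitude(trace: RespiratoryTrace) -> float:
    """Mean over cycles of the per-cycle peak-to-trough excursion, mm.

    This is the amplitude statistic used to program the phantom: unlike the
    raw global maximum it is inflated only mildly by transient sharp inhales.
    """
    cycles = detect_cycles(trace)
    if cycles.n_cycles == 0:
        raise NoCyclesError("no complete breathing cycle detected")
    return float(np.mean(cycles.cycle_pp))


def scale_to_mean_amplitude(trace: RespiratoryTrace, target_mm: float) -> RespiratoryTrace:
    """Rescale a mean-centered copy of the trace so its mean per-cycle
    excursion equals ``target_mm``."""
    current = mean_max_amplitude(trace)  # raises NoCyclesError on flat traces
    if current <= 0:
        raise NoCyclesError("trace has zero cycle amplitude")
    scaled = (trace.a - trace.a.mean()) * (target_mm / current)
    return replace(trace, a=scaled)


def classify_pattern(
    trace: RespiratoryTrace,
    regular_cv: float = 0.10,
    irregular_cv: float = 0.25,
    spike_factor: float = 2.0,
) -> str:
    """Classify a trace as regular / semiregular / irregular.

    Operationalized with coefficients of variation of per-cycle excursion and
    of cycle period: regular breathing keeps both low; semiregular breathing
    keeps phase (period) stable but drifts in amplitude; irregular breathing
    deviates in both and may contain sharp-inhale spikes. Fewer than 3 cycles
    returns ``"unknown"``.
    """
    cycles = detect_cycles(trace)
    if cycles.n_cycles < 3:
        return "unknown"
    amp = cycles.cycle_pp
    periods = np.diff(trace.t[cycles.peak_indices])
    cv_amp = float(np.std(amp) / np.mean(amp))
    cv_per = float(np.std(periods) / np.mean(periods))
    spike = bool(np.any(amp > spike_factor * np.median(amp)))
    if cv_amp > irregular_cv or cv_per > irregular_cv or spike:
        return "irregular"
    if cv_amp < regular_cv and cv_per < regular_cv:
        return "regular"
    return "semiregular"


def _cycle_shape(tau: np.ndarray, inhale_speed: float = 0.85, rest_flatness: float = 1.3) -> np.ndarray:
    """Breathing-like unit cycle on tau in [0, 1): 0 at end-exhale, 1 at peak.

    A warped raised cosine: inhale slightly faster than exhale, with a
    flattened end-exhale rest phase.
    """
    warped = tau**inhale_speed
    return (0.5 - 0.5 * np.cos(2 * np.pi * warped)) ** rest_flatness


def generate_patient_like(
    category: str,
    mean_pp_mm: float = 10.0,
    period_s: float = 4.0,
    duration_s: float = 120.0,
    dt: float = 0.02,
    seed: int | None = 0,
) -> RespiratoryTrace:
    """Synthesize an RPM-style patient trace of the requested regularity class.

    Cycle-by-cycle construction: each cycle gets a period and an amplitude
    drawn according to the class (small jitter for regular; slow amplitude
    drift for semiregular; heavy jitter plus sharp-inhale spikes and a pause
    for irregular), then the whole trace is rescaled so its mean per-cycle
    excursion equals ``mean_pp_mm``.
    """
    if category not in ("regular", "semiregular", "irregular"):
        raise ValueError("category must be regular, semiregular or irregular")
    rng = np.random.default_rng(seed)
    n_cycles = max(3, int(np.ceil(duration_s / period_s)) + 2)
    idx = np.arange(n_cycles)
    if category == "regular":
        periods = period_s * (1 + 0.03 * rng.standard_normal(n_cycles))
        amps = 1 + 0.04 * rng.standard_normal(n_cycles)
    elif category == "semiregular":
        periods = period_s * (1 + 0.03 * rng.standard_normal(n_cycles))
        # slow sinusoidal drift plus mild AR(1) wander in amplitude
        drift = 0.22 * np.sin(2 * np.pi * idx / n_cycles * 1.5 + rng.uniform(0, 2 * np.pi))
        wander = np.zeros(n_cycles)
        for i in range(1, n_cycles):
            wander[i] = 0.85 * wander[i - 1] + 0.05 * rng.standard_normal()
        amps = 1 + drift + wander
    else:
        periods = period_s * (1 + 0.22 * rng.standard_normal(n_cycles))
        amps = 1 + 0.25 * rng.standard_normal(n_cycles)
        n_spikes = max(1, n_cycles // 12)
        spike_at = rng.choice(np.arange(1, n_cycles - 1), size=n_spikes, replace=False)
        amps[spike_at] *= rng.uniform(2.5, 3.2, size=n_spikes)
        pause_at = int(rng.integers(1, n_cycles - 1))
        periods[pause_at] += rng.uniform(3.0, 6.0)  # breathing disruption
        amps[pause_at] *= 0.5
    periods = np.clip(periods, 1.5, None)
    amps = np.clip(amps, 0.15, None)

    t = np.arange(int(round(duration_s / dt)) + 1) * dt
    a = np.zeros_like(t)
    t0 = 0.0
    for T, A in zip(periods, amps):
        sel = (t >= t0) & (t < t0 + T)
        if sel.any():
            tau = (t[sel] - t0) / T
            a[sel] = A * _cycle_shape(tau)
        t0 += T
        if t0 > t[-1]:
            break
    trace = RespiratoryTrace(t, a, dt, label=f"patient_{category}_{seed}", category=category)
    return replace(scale_to_mean_amplitude(trace, mean_pp_mm), category=category)


def write_trace_csv(trace: RespiratoryTrace, path) -> None:
    """Write a two-column waveform CSV (``time_s,amp_mm``)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "amp_mm"])
        for ti, ai in zip(trace.t, trace.a):
            w.writerow([repr(float(ti)), repr(float(ai))])


def read_trace_csv(path, label: str | None = None) -> RespiratoryTrace:
    """Read a two-column time/amplitude CSV (header optional).

    Time must be strictly increasing and uniform; sampling jitter below
    1e-6 s is absorbed by inferring dt from the median spacing.
    """
    times: list[float] = []
    amps: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise TraceParseError("expected two columns", lineno)
            try:
                ti, ai = float(row[0]), float(row[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise TraceParseError(f"non-numeric row {row!r}", lineno) from None
            times.append(ti)
            amps.append(ai)
    if len(times) < 2:
        raise TraceParseError("need at least two samples")
    t = np.asarray(times)
    a = np.asarray(amps)
    d = np.diff(t)
    bad = np.nonzero(d <= 0)[0]
    if len(bad):
        raise TraceParseError("time column not strictly increasing", int(bad[0]) + 2)
    dt = float(np.median(d))
    if np.max(np.abs(d - dt)) > 1e-6:
        raise TraceParseError("time column not uniformly sampled (jitter > 1e-6 s)")
    t = t[0] + np.arange(len(t)) * dt  # regularize sub-1e-6 jitter
    return RespiratoryTrace(t, a, dt, label=label or str(path))
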