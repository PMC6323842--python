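"""Breathing-trace processing.

Covers the steps between a raw displacement trace and the quantities
the dosimetric pipeline consumes:

* zero-phase low-pass filtering of noisy fiducial traces,
* cycle segmentation at peaks and valleys,
* ten-interval phase sampling of a cycle (the rule a phase-sorted
  4DCT applies: a cycle span is divided into 10 equal time intervals
  and the displacement at each interval midpoint is the tumor position
  of that phase),
* the empirical tumor-position probability density on integer-mm bins
  and its central coverage interval, which drives the robust-ITV
  extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .motion import BreathingTrace

__all__ = [
    "CycleSegmentation",
    "PositionPdf",
    "lowpass_filter",
    "segment_cycles",
    "phase_sample_segment",
    "phase_sample_cycles",
    "cycle_amplitudes",
    "cycle_periods",
    "empirical_position_pdf",
    "coverage_interval",
    "round_half_up",
]


def round_half_up(x, bin_mm: float = 1.0):
    """Round to the nearest multiple of ``bin_mm``, half-up (toward +inf).

    A 1e-9 guard absorbs representation error in values that are
    exactly half a bin (e.g. -2.5 stored as -2.5000000000000004).
    """
    return np.floor(np.asarray(x) / bin_mm + 0.5 + 1e-9) * bin_mm


@dataclass(frozen=True)
class CycleSegmentation:
    """Extrema and cycle spans of a breathing trace.

    ``segments`` are consecutive extremum pairs (half cycles, peak-to-
    valley or valley-to-peak); ``full_cycles`` pair consecutive peaks.
    ``boundary_indices`` marks extrema that sit on the first or last
    trace sample: they are detected (the generator starts every session
    at a peak, and a session may end exactly on one) but a full cycle
    that *ends* on the trace boundary may be an artifact of mid-cycle
    truncation, so cycle-wise statistics exclude it.
    """

    peak_indices: np.ndarray
    valley_indices: np.ndarray
    segments: tuple[tuple[int, int], ...]
    full_cycles: tuple[tuple[int, int], ...]
    boundary_indices: frozenset[int]

    def interior_full_cycles(self, n_samples: int) -> tuple[tuple[int, int], ...]:
        """Full cycles that do not end on the final trace sample."""
        last = n_samples - 1
        return tuple(
            (s, e)
            for s, e in self.full_cycles
            if not (e == last and e in self.boundary_indices)
        )


def lowpass_filter(
    trace: BreathingTrace, cutoff_hz: float = 1.0, order: int = 4
) -> BreathingTrace:
    """Zero-phase Butterworth low-pass filter.

    Forward-backward filtering leaves extremum timestamps unshifted,
    which matters because phase sampling is anchored on peak/valley
    times.  Breathing fundamentals (~0.2-0.5 Hz) and their first
    harmonic pass essentially unattenuated at the default 1 Hz cutoff.
    """
    fs = 1.0 / trace.sample_interval_s
    nyquist = fs / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff_hz must lie in (0, Nyquist={nyquist:g} Hz), got {cutoff_hz!r}"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    z = signal.sosfiltfilt(sos, trace.displacement_mm)
    return BreathingTrace(trace.time_s, z, trace.sample_interval_s)


def _find_extrema(z: np.ndarray, prominence: float, kind: str) -> np.ndarray:
    """Local maxima (kind='peak') or minima of z, boundary-aware.

    The array is padded with a value beyond the data range so that a
    first/last sample that dominates its single neighbor is reported
    as an extremum too.
    """
    y = z if kind == "peak" else -z
    pad = y.min() - prominence - 1.0
    padded = np.concatenate([[pad], y, [pad]])
    idx, _ = signal.find_peaks(padded, prominence=prominence)
    return idx - 1


def segment_cycles(
    trace: BreathingTrace, *, prominence: float | None = None
) -> CycleSegmentation:
    """Segment a (filtered or noise-free) trace into breathing cycles.

    Extrema are detected with a minimum prominence (default 20% of the
    displacement inter-quartile range) and forced to alternate: of two
    neighboring same-type extrema the more extreme one is kept, ties
    resolved to the earlier sample.
    """
    z = trace.displacement_mm
    if prominence is None:
        q75, q25 = np.percentile(z, [75, 25])
        prominence = 0.2 * (q75 - q25)
    if prominence <= 0:
        raise ValueError("trace has no dynamic range; cannot segment cycles")
    peaks = _find_extrema(z, prominence, "peak")
    valleys = _find_extrema(z, prominence, "valley")
    if peaks.size == 0 or valleys.size == 0:
        raise ValueError(
            f"no {'peak' if peaks.size == 0 else 'valley'} found at prominence "
            f"{prominence:g} mm; is the trace filtered?"
        )

    # merge into one alternating sequence
    extrema = [(int(i), "peak") for i in peaks] + [(int(i), "valley") for i in valleys]
    extrema.sort()
    kept: list[tuple[int, str]] = []
    for idx, kind in extrema:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (z[idx] > z[prev]) if kind == "peak" else (z[idx] < z[prev])
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))

    peak_idx = np.array([i for i, k in kept if k == "peak"], dtype=int)
    valley_idx = np.array([i for i, k in kept if k == "valley"], dtype=int)
    order = [i for i, _ in kept]
    segments = tuple(zip(order[:-1], order[1:]))
    full_cycles = tuple(zip(peak_idx[:-1], peak_idx[1:]))
    last = trace.n_samples - 1
    boundary = frozenset(i for i, _ in kept if i in (0, last))
    return CycleSegmentation(peak_idx, valley_idx, segments, full_cycles, boundary)


def phase_sample_segment(
    trace: BreathingTrace, segment: tuple[int, int], n_phases: int = 10
) -> np.ndarray:
    """Phase-sample one cycle span per the midpoint rule.

    The span [t_S, t_E] is divided into ``n_phases`` equal time
    intervals; the sample of phase i is the displacement at the i-th
    interval midpoint, linearly interpolated between trace samples.
    """
    start, end = segment
    t_s = float(trace.time_s[start])
    t_e = float(trace.time_s[end])
    if not t_e > t_s:
        raise ValueError(f"degenerate segment: t_E={t_e} <= t_S={t_s}")
    width = (t_e - t_s) / n_phases
    midpoints = t_s + (np.arange(n_phases) + 0.5) * width
    return np.interp(midpoints, trace.time_s, trace.displacement_mm)


def phase_sample_cycles(
    trace: BreathingTrace,
    seg: CycleSegmentation,
    *,
    mode: str = "full",
    n_phases: int = 10,
    include_boundary_final: bool = False,
) -> np.ndarray:
    """Phase samples of every cycle of a trace, shape (n_cycles, n_phases).

    ``mode='full'`` applies the midpoint rule to each peak-to-peak
    cycle (the common clinical convention); ``mode='half'`` applies it
    to each peak--valley half cycle instead.  A final cycle ending on
    the trace boundary is excluded unless requested, since it may stem
    from mid-cycle truncation of the session.
    """
    if mode == "full":
        spans = (
            seg.full_cycles
            if include_boundary_final
            else seg.interior_full_cycles(trace.n_samples)
        )
    elif mode == "half":
        spans = seg.segments
    else:
        raise ValueError("mode must be 'full' or 'half'")
    if not spans:
        raise ValueError("no cycle spans available for phase sampling")
    return np.vstack([phase_sample_segment(trace, s, n_phases) for s in spans])


def cycle_amplitudes(trace: BreathingTrace, seg: CycleSegmentation) -> np.ndarray:
    """Peak-to-peak amplitude of each full cycle, valley-anchored.

    In the cos^4 model the valley displacement is exactly -A/2, and the
    valley lies in the interior of its cycle, whereas the displacement
    at a detected peak is ambiguous between the two adjoining cycles
    (the junction jumps by half their amplitude difference, and the
    local maximum always belongs to the larger one).  Measuring
    A = -2 * min(Z) per cycle is therefore unbiased for heterogeneous
    sessions.  Cycles ending on the trace boundary are excluded.
    """
    z = trace.displacement_mm
    spans = seg.interior_full_cycles(trace.n_samples)
    return np.array([-2.0 * z[s : e + 1].min() for s, e in spans])


def cycle_periods(trace: BreathingTrace, seg: CycleSegmentation) -> np.ndarray:
    """Duration of each full cycle (boundary-terminated ones excluded)."""
    t = trace.time_s
    spans = seg.interior_full_cycles(trace.n_samples)
    return np.array([t[e] - t[s] for s, e in spans])


# ---------------------------------------------------------------------------
# Position probability density and coverage interval.


@dataclass(frozen=True)
class PositionPdf:
    """Empirical tumor-position distribution on integer-mm bins."""

    positions_mm: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm)
        prob = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "probabilities", prob)
        if pos.size != prob.size or pos.size == 0:
            raise ValueError("positions and probabilities must be equal-length, nonempty")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be sorted ascending and unique")
        if np.any(prob < 0):
            raise ValueError("probabilities must be >= 0")
        if abs(prob.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


def empirical_position_pdf(trace: BreathingTrace, bin_mm: float = 1.0) -> PositionPdf:
    """Occupancy distribution of the tumor position.

    Displacements are rounded half-up to the nearest ``bin_mm``; the
    probability of a bin is the fraction of trace samples in it.
    """
    binned = round_half_up(trace.displacement_mm, bin_mm)
    positions, counts = np.unique(binned, return_counts=True)
    if float(bin_mm).is_integer():
        positions = positions.astype(int)
    return PositionPdf(positions, counts / counts.sum())


def coverage_interval(pdf: PositionPdf, coverage: float = 0.8) -> tuple[int, int]:
    """Equal-tail central interval holding ``coverage`` probability mass.

    ``lo`` is the smallest position whose cumulative probability
    reaches (1-coverage)/2; ``hi`` the smallest reaching
    1-(1-coverage)/2.  Returned in integer mm (bin units).
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    tail = (1.0 - coverage) / 2.0
    cum = np.cumsum(pdf.probabilities)
    lo_i = int(np.argmax(cum >= tail - 1e-12))
    hi_i = int(np.argmax(cum >= 1.0 - tail - 1e-12))
    lo = pdf.positions_mm[lo_i]
    hi = pdf.positions_mm[hi_i]
    return int(lo), int(hi)
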