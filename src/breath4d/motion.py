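"""Synthetic respiratory tumor-motion generation.

Lung tumors move predominantly along the superior--inferior (SI) axis.
Within one breathing cycle of peak-to-peak amplitude ``A`` (mm) and
period ``P`` (s) the SI displacement is modelled as

    Z(t) = A * (cos^4(pi * t / P) - 1/2),    t in [0, P),

so a cycle starts at its inhale peak (+A/2), dwells near the exhale
valley (-A/2, where the cos^4 shape is flattest, mimicking the long
end-exhale phase of real breathing) and returns to the peak.  A
session concatenates cycles whose ``(A, P)`` are drawn independently
from N(mu_A, sigma_A) and N(mu_P, sigma_P); the heterogeneity of the
pattern is controlled through the coefficients of variation
``sigma_A / mu_A`` and ``sigma_P / mu_P``.

Two kinds of traces are produced:

* densely sampled noise-free simulation traces (default 0.02 s grid),
  used for the scenario sweeps, and
* "fiducial-like" patient traces: the same backbone resampled at a
  fluoroscopic 30 Hz with additive Gaussian measurement noise.

The module also carries two printed parameter tables as plain data:
a ten-scenario grid spanning mean amplitude 5--20 mm, amplitude CV
0.15--0.35, mean period 3--5 s and period CV 0.1--0.3, and per-fraction
motion statistics measured from implanted-fiducial tracking of three
lung SBRT patients (five fractions each).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MotionParams",
    "BreathingTrace",
    "PatientLikeParams",
    "SCENARIO_GRID",
    "PATIENT_MOTION_CHARACTERISTICS",
    "sample_cycle_params",
    "draw_session_cycles",
    "simulate_trace",
    "generate_scenario_bank",
    "generate_patient_like_trace",
    "scenario_params",
    "patient_fraction_params",
    "write_trace_csv",
    "read_trace_csv",
]

#: Default floors below which Gaussian draws are rejected and redrawn.
MIN_AMPLITUDE_MM = 0.5
MIN_PERIOD_S = 0.5

#: Default temporal sampling of simulated (noise-free) traces, s.
DEFAULT_SAMPLE_INTERVAL_S = 0.02


@dataclass(frozen=True)
class MotionParams:
    """Parameters of one breathing session.

    Parameters
    ----------
    mean_amplitude_mm : float
        Mean peak-to-peak cycle amplitude ``mu_A`` (mm).
    amplitude_cv : float
        Coefficient of variation of the amplitude; ``sigma_A = cv * mu_A``.
    mean_period_s : float
        Mean cycle period ``mu_P`` (s).
    period_cv : float
        Coefficient of variation of the period; ``sigma_P = cv * mu_P``.
    duration_s : float
        Session length (s).  A 4DCT acquisition session is ~100 s.
    seed : int
        Seed of the per-session random generator.
    """

    mean_amplitude_mm: float
    amplitude_cv: float = 0.0
    mean_period_s: float = 4.0
    period_cv: float = 0.0
    duration_s: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_amplitude_mm > 0:
            raise ValueError("mean_amplitude_mm must be > 0")
        if not self.mean_period_s > 0:
            raise ValueError("mean_period_s must be > 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if self.period_cv < 0:
            raise ValueError("period_cv must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")

    @property
    def amplitude_sd_mm(self) -> float:
        return self.amplitude_cv * self.mean_amplitude_mm

    @property
    def period_sd_s(self) -> float:
        return self.period_cv * self.mean_period_s


@dataclass(frozen=True)
class BreathingTrace:
    """A sampled SI tumor-displacement trace.

    ``displacement_mm`` is positive toward superior.  Sampling must be
    uniform, starting at t = 0.
    """

    time_s: np.ndarray
    displacement_mm: np.ndarray
    sample_interval_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        z = np.asarray(self.displacement_mm, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "displacement_mm", z)
        if t.ndim != 1 or z.ndim != 1 or t.size != z.size:
            raise ValueError("time_s and displacement_mm must be equal-length 1-D arrays")
        if t.size < 2:
            raise ValueError("a trace needs at least two samples")
        if abs(t[0]) > 1e-9:
            raise ValueError("time must start at 0")
        steps = np.diff(t)
        if np.any(np.abs(steps - self.sample_interval_s) > 1e-9):
            raise ValueError("sampling must be uniform at sample_interval_s")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1])


@dataclass(frozen=True)
class PatientLikeParams:
    """Parameters of a fiducial-like noisy patient trace."""

    motion: MotionParams
    noise_sd_mm: float = 0.5
    sample_rate_hz: float = 30.0
    n_fractions: int = 5

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


# ---------------------------------------------------------------------------
# Printed parameter tables.

#: Ten-scenario grid of breathing-pattern parameters: each row gives
#: (mean excursion mm, sd of excursion / mean excursion, mean period s,
#: sd of period / mean period).  Ten replicate sessions per row make a
#: 100-curve scenario bank.
SCENARIO_GRID: tuple[dict, ...] = tuple(
    dict(
        zip(
            ("mean_excursion_mm", "excursion_cv", "mean_period_s", "period_cv"),
            row,
        )
    )
    for row in [
        (5.0, 0.25, 4.0, 0.2),
        (10.0, 0.25, 4.0, 0.2),
        (15.0, 0.25, 4.0, 0.2),
        (20.0, 0.25, 4.0, 0.2),
        (15.0, 0.15, 4.0, 0.2),
        (15.0, 0.35, 4.0, 0.2),
        (15.0, 0.25, 3.0, 0.2),
        (15.0, 0.25, 5.0, 0.2),
        (15.0, 0.25, 4.0, 0.1),
        (15.0, 0.25, 4.0, 0.3),
    ]
)

#: Per-fraction SI motion statistics of three fiducial-tracked lung SBRT
#: patients (5 treatment fractions each), same column meaning as
#: SCENARIO_GRID.  Patient #1 breathes regularly (CV ~0.1), patient #2
#: has ~10 mm excursion with CV ~0.22, patient #3 ~15 mm with CV ~0.22.
PATIENT_MOTION_CHARACTERISTICS: dict[int, tuple[dict, ...]] = {
    1: tuple(
        dict(zip(("mean_excursion_mm", "excursion_cv", "mean_period_s", "period_cv"), row))
        for row in [
            (10.11, 0.12, 4.85, 0.12),
            (10.32, 0.09, 4.65, 0.09),
            (10.14, 0.12, 4.95, 0.08),
            (9.88, 0.11, 5.15, 0.09),
            (8.59, 0.09, 5.05, 0.12),
        ]
    ),
    2: tuple(
        dict(zip(("mean_excursion_mm", "excursion_cv", "mean_period_s", "period_cv"), row))
        for row in [
            (10.21, 0.23, 3.78, 0.05),
            (9.92, 0.20, 3.81, 0.09),
            (10.53, 0.23, 3.85, 0.09),
            (10.62, 0.25, 3.39, 0.15),
            (10.05, 0.22, 3.78, 0.05),
        ]
    ),
    3: tuple(
        dict(zip(("mean_excursion_mm", "excursion_cv", "mean_period_s", "period_cv"), row))
        for row in [
            (15.28, 0.23, 2.71, 0.08),
            (14.36, 0.20, 2.79, 0.08),
            (16.21, 0.21, 3.18, 0.11),
            (15.88, 0.23, 3.11, 0.10),
            (15.20, 0.22, 3.06, 0.10),
        ]
    ),
}

_ROW_FIELDS = ("mean_excursion_mm", "excursion_cv", "mean_period_s", "period_cv")


def _validate_row(row: dict, index: int) -> None:
    for name in _ROW_FIELDS:
        if name not in row:
            raise ValueError(f"scenario row {index} is missing field '{name}'")
        value = row[name]
        if not np.isfinite(value):
            raise ValueError(f"scenario row {index} field '{name}' is not finite")
    if row["mean_excursion_mm"] <= 0:
        raise ValueError(f"scenario row {index} field 'mean_excursion_mm' must be > 0")
    if row["mean_period_s"] <= 0:
        raise ValueError(f"scenario row {index} field 'mean_period_s' must be > 0")
    if row["excursion_cv"] < 0:
        raise ValueError(f"scenario row {index} field 'excursion_cv' must be >= 0")
    if row["period_cv"] < 0:
        raise ValueError(f"scenario row {index} field 'period_cv' must be >= 0")


def scenario_params(
    row: dict, *, duration_s: float = 100.0, seed: int = 0, index: int = 0
) -> MotionParams:
    """Turn one scenario-grid row into :class:`MotionParams`."""
    _validate_row(row, index)
    return MotionParams(
        mean_amplitude_mm=float(row["mean_excursion_mm"]),
        amplitude_cv=float(row["excursion_cv"]),
        mean_period_s=float(row["mean_period_s"]),
        period_cv=float(row["period_cv"]),
        duration_s=duration_s,
        seed=seed,
    )


def patient_fraction_params(
    patient: int, fraction: int, *, duration_s: float = 100.0, seed: int = 0
) -> MotionParams:
    """Motion parameters of one treatment fraction of a reference patient.

    ``fraction`` is 1-based, matching the clinical numbering.
    """
    rows = PATIENT_MOTION_CHARACTERISTICS[patient]
    return scenario_params(rows[fraction - 1], duration_s=duration_s, seed=seed)


# ---------------------------------------------------------------------------
# Cycle drawing and trace synthesis.


def sample_cycle_params(
    params: MotionParams,
    rng: np.random.Generator,
    *,
    min_amplitude_mm: float = MIN_AMPLITUDE_MM,
    min_period_s: float = MIN_PERIOD_S,
) -> tuple[float, float]:
    """Draw one cycle's (amplitude, period) pair.

    Draws are Gaussian; non-physical values (amplitude <= 0.5 mm,
    period <= 0.5 s) are rejected and redrawn rather than clipped, so
    the resulting truncated distributions carry no point mass at the
    floor.  Consuming the generator advances it deterministically.
    """
    amplitude = rng.normal(params.mean_amplitude_mm, params.amplitude_sd_mm)
    while amplitude <= min_amplitude_mm:
        amplitude = rng.normal(params.mean_amplitude_mm, params.amplitude_sd_mm)
    period = rng.normal(params.mean_period_s, params.period_sd_s)
    while period <= min_period_s:
        period = rng.normal(params.mean_period_s, params.period_sd_s)
    return float(amplitude), float(period)


def draw_session_cycles(
    params: MotionParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the cycle sequence covering one session.

    Returns a frame with columns ``start_s``, ``amplitude_mm``,
    ``period_s``.  Cycles are drawn until their cumulative duration
    exceeds ``duration_s``; the final cycle is in general cut mid-way
    by the session end.
    """
    starts, amplitudes, periods = [], [], []
    t = 0.0
    # small epsilon so the sample exactly at duration_s has a cycle
    while t <= params.duration_s + 1e-9:
        a, p = sample_cycle_params(params, rng)
        starts.append(t)
        amplitudes.append(a)
        periods.append(p)
        t += p
    return pd.DataFrame(
        {"start_s": starts, "amplitude_mm": amplitudes, "period_s": periods}
    )


def _evaluate_cycles(cycles: pd.DataFrame, t: np.ndarray) -> np.ndarray:
    starts = cycles["start_s"].to_numpy()
    amp = cycles["amplitude_mm"].to_numpy()
    per = cycles["period_s"].to_numpy()
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    local = t - starts[idx]
    return amp[idx] * (np.cos(np.pi * local / per[idx]) ** 4 - 0.5)


def simulate_trace(
    params: MotionParams,
    *,
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S,
    cycles: pd.DataFrame | None = None,
) -> BreathingTrace:
    """Synthesize one noise-free heterogeneous breathing trace.

    Each cycle evaluates the cos^4 displacement model with its own
    (A, P) on local time t in [0, P); cycles are concatenated at their
    peaks, so the junction discontinuity is bounded by half the
    amplitude difference of the adjoining cycles.  The trace covers
    [0, duration_s] inclusive and is bit-identical for a fixed seed.

    A pre-drawn cycle table may be passed to evaluate the same session
    on a different sampling grid.
    """
    if cycles is None:
        rng = np.random.default_rng(params.seed)
        cycles = draw_session_cycles(params, rng)
    n = int(np.floor(params.duration_s / sample_interval_s + 1e-9)) + 1
    t = np.arange(n) * sample_interval_s
    z = _evaluate_cycles(cycles, t)
    return BreathingTrace(t, z, sample_interval_s)


def generate_patient_like_trace(p: PatientLikeParams) -> BreathingTrace:
    """Synthesize a jagged fiducial-like trace.

    The cos^4 backbone is evaluated directly on the fluoroscopic
    sampling grid (default 30 Hz) and i.i.d. Gaussian measurement
    noise of sd ``noise_sd_mm`` is added.  With zero noise the result
    equals :func:`simulate_trace` resampled on the same grid.
    """
    rng = np.random.default_rng(p.motion.seed)
    cycles = draw_session_cycles(p.motion, rng)
    dt = 1.0 / p.sample_rate_hz
    trace = simulate_trace(p.motion, sample_interval_s=dt, cycles=cycles)
    if p.noise_sd_mm > 0:
        noisy = trace.displacement_mm + rng.normal(
            0.0, p.noise_sd_mm, size=trace.n_samples
        )
        trace = BreathingTrace(trace.time_s, noisy, dt)
    return trace


def generate_scenario_bank(
    rows=None,
    replicates: int = 10,
    base_seed: int = 0,
    *,
    duration_s: float = 100.0,
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S,
) -> list[dict]:
    """Generate the replicate bank of heterogeneous breathing curves.

    One trace per (scenario row, replicate); with the default grid of
    ten rows and ten replicates this is the 100-curve bank.  Seeds are
    derived as ``base_seed + row_index * 1000 + replicate`` and recorded
    in each entry, so the bank is reproducible entry by entry.

    Returns a list of dicts with keys ``trace``, ``row`` (parameter
    dict), ``row_index``, ``replicate``, ``seed``.
    """
    if rows is None:
        rows = SCENARIO_GRID
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    bank = []
    for i, row in enumerate(rows):
        _validate_row(row, i)
        for rep in range(replicates):
            seed = base_seed + i * 1000 + rep
            params = scenario_params(row, duration_s=duration_s, seed=seed, index=i)
            trace = simulate_trace(params, sample_interval_s=sample_interval_s)
            bank.append(
                {
                    "trace": trace,
                    "row": dict(row),
                    "row_index": i,
                    "replicate": rep,
                    "seed": seed,
                }
            )
    return bank


# ---------------------------------------------------------------------------
# Trace CSV I/O (lossless round-trip at full double precision).


def write_trace_csv(trace: BreathingTrace, path) -> None:
    header = "time_s,displacement_mm"
    data = np.column_stack([trace.time_s, trace.displacement_mm])
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header=header, comments="")


def read_trace_csv(path) -> BreathingTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, z = data[:, 0], data[:, 1]
    return BreathingTrace(t, z, float(t[1] - t[0]))
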