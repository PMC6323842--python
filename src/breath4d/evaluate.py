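"""Discrepancy metrics, parameter sweeps and plan comparison.

The central quantity is the per-curve worst-case relative deviation of
the phase-sorted 4D dose from the true accumulated dose,

    dDx_bar = sum_j  max_k |D4D_{x,j,k} - Dtrue_{x,j}|
              -----------------------------------------  * 100%,
                        J * Dtrue_{x,j}

where j runs over the J curves (simulated sessions or treatment
fractions), k over the K_j breathing cycles of curve j, and x is the
DVH coverage level (95 or 99).  The module also runs the scenario
sweeps (amplitude, amplitude CV, period, period CV), fits the linear
trends, and compares standard vs pdf-extended robust plans with paired
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import accumulate as acc
from . import motion, processing
from .dose import PlanSpec, plan_dose
from .phantom import PhantomGrid, TargetGeometry, build_itv, make_gtv_mask
from .processing import round_half_up

__all__ = [
    "TrendFit",
    "PairedComparison",
    "build_discrepancy_records",
    "worst_case_delta",
    "traditional_phase_positions",
    "ShiftDoseSampler",
    "curve_dose_metrics",
    "run_sweep",
    "fit_trend",
    "compare_robust",
]


def build_discrepancy_records(per_curve: list[dict]) -> pd.DataFrame:
    """Assemble the tidy per-curve/per-cycle discrepancy table.

    ``per_curve`` holds one dict per curve j with keys ``d4d`` (mapping
    metric x -> array of per-cycle D4D_x values, % of prescription) and
    ``dtrue`` (mapping x -> scalar Dtrue_x).
    """
    rows = []
    for j, curve in enumerate(per_curve):
        for x, d4d_values in curve["d4d"].items():
            dtrue = float(curve["dtrue"][x])
            for k, d4d in enumerate(np.atleast_1d(d4d_values)):
                rows.append(
                    {
                        "curve": j,
                        "segment": k,
                        "metric": int(x),
                        "d4d_pct": float(d4d),
                        "dtrue_pct": dtrue,
                        "abs_diff_pct": abs(float(d4d) - dtrue),
                    }
                )
    return pd.DataFrame(rows)


def worst_case_delta(records: pd.DataFrame, metric: int) -> float:
    """Average-over-curves worst-case relative deviation, in percent.

    For each curve the worst cycle (largest |D4D_x - Dtrue_x|) is
    taken relative to that curve's Dtrue_x; the per-curve worst cases
    are averaged over the J curves.  The ratio form makes the result
    identical whether doses are expressed in Gy or % of prescription.
    """
    sub = records[records["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no records for metric D{metric}")
    if (sub["dtrue_pct"] <= 0).any():
        raise ValueError("Dtrue must be positive for the relative deviation")
    per_curve = sub.groupby("curve").apply(
        lambda g: g["abs_diff_pct"].max() / g["dtrue_pct"].iloc[0],
        include_groups=False,
    )
    return float(per_curve.mean() * 100.0)


# ---------------------------------------------------------------------------
# Pipeline plumbing shared by the sweeps and the robust comparison.


def traditional_phase_positions(
    amplitude_mm: float, period_s: float = 4.0, *, phase_mode: str = "full"
) -> np.ndarray:
    """Integer-mm phase positions of a homogeneous planning curve.

    Reproduces the planning 4DCT: a zero-variance cos^4 curve of the
    given amplitude is simulated, one interior cycle segmented, and its
    ten phase-sampled displacements rounded to the 1-mm image bank.
    """
    params = motion.MotionParams(
        mean_amplitude_mm=amplitude_mm,
        amplitude_cv=0.0,
        mean_period_s=period_s,
        period_cv=0.0,
        duration_s=3.0 * period_s,
        seed=0,
    )
    trace = motion.simulate_trace(params)
    seg = processing.segment_cycles(trace)
    samples = processing.phase_sample_cycles(trace, seg, mode=phase_mode)
    return np.unique(round_half_up(samples[0]).astype(int))


class ShiftDoseSampler:
    """Caches per-voxel dose vectors per integer-mm SI shift.

    The accumulation displacements are rounded to integer mm, so for a
    fixed dose field and reference GTV only 31 distinct shift vectors
    ever occur; caching them makes whole-trace accumulation cheap.
    """

    def __init__(self, field, gtv_ref):
        self.field = field
        self.gtv_ref = gtv_ref
        self._cache: dict[float, np.ndarray] = {}

    def dose_vector(self, z_mm: float) -> np.ndarray:
        key = float(z_mm)
        if key not in self._cache:
            self._cache[key] = acc.sample_dose_at_displacement(
                self.field, self.gtv_ref, key
            )
        return self._cache[key]

    def mean_dose(self, displacements_mm) -> acc.AccumulatedDose:
        z = np.atleast_1d(np.asarray(displacements_mm, dtype=float))
        unique, counts = np.unique(z, return_counts=True)
        mean = np.zeros(int(self.gtv_ref.mask.sum()))
        for zi, w in zip(unique, counts / z.size):
            mean += w * self.dose_vector(zi)
        return acc.AccumulatedDose(mean, self.gtv_ref, int(z.size), z)


def curve_dose_metrics(
    trace,
    sampler: ShiftDoseSampler,
    spec: PlanSpec,
    *,
    metrics=(99, 95),
    dtrue_interval_s: float = 0.4,
    phase_mode: str = "full",
) -> dict:
    """Dtrue_x and per-cycle D4D_x of one breathing curve.

    The trace is segmented into full cycles (a final cycle truncated
    by the session end is excluded); each cycle's ten phase samples are
    rounded to integer mm and accumulated (I = 10), the whole trace is
    accumulated on the uniform ``dtrue_interval_s`` grid.
    """
    from .phantom import SI_RANGE_MM

    n = int(np.floor(trace.duration_s / dtrue_interval_s + 1e-9))
    t = (np.arange(n) + 0.5) * dtrue_interval_s
    z_true = np.clip(
        round_half_up(np.interp(t, trace.time_s, trace.displacement_mm)),
        *SI_RANGE_MM,
    )
    acc_true = sampler.mean_dose(z_true)

    seg = processing.segment_cycles(trace)
    phase_sets = processing.phase_sample_cycles(trace, seg, mode=phase_mode)
    d4d = {x: [] for x in metrics}
    for row in phase_sets:
        z = np.clip(round_half_up(row), *SI_RANGE_MM)
        acc_4d = sampler.mean_dose(z)
        for x in metrics:
            d4d[x].append(acc.dose_at_volume(acc_4d, x, spec.prescription_gy))
    return {
        "d4d": {x: np.array(v) for x, v in d4d.items()},
        "dtrue": {
            x: acc.dose_at_volume(acc_true, x, spec.prescription_gy) for x in metrics
        },
        "n_cycles": phase_sets.shape[0],
    }


def run_sweep(
    scenarios=None,
    replicates: int = 10,
    *,
    diameter_cm: float = 3.0,
    spec: PlanSpec | None = None,
    grid: PhantomGrid | None = None,
    base_seed: int = 0,
    metrics=(99, 95),
    duration_s: float = 100.0,
    dtrue_interval_s: float = 0.4,
    phase_mode: str = "full",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the scenario sweep end to end.

    For every scenario row a traditional plan is built on a homogeneous
    planning curve of amplitude mu_A (period 4 s); each replicate
    heterogeneous curve is then evaluated against it (Dtrue once,
    D4D per cycle) and the worst-case deltas aggregated over the J =
    ``replicates`` curves.

    Returns ``(summary, records)``: one summary row per scenario with
    the delta for each metric, plus the tidy per-cycle record table.
    """
    if scenarios is None:
        scenarios = motion.SCENARIO_GRID
    spec = spec or PlanSpec()
    grid = grid or PhantomGrid()
    gtv_ref = make_gtv_mask(grid, TargetGeometry(diameter_cm, 0))

    plan_cache: dict[tuple, object] = {}
    summaries, all_records = [], []
    for i, row in enumerate(scenarios):
        positions = traditional_phase_positions(
            row["mean_excursion_mm"], phase_mode=phase_mode
        )
        key = (tuple(positions), diameter_cm, spec)
        if key not in plan_cache:
            itv = build_itv(grid, diameter_cm, positions)
            plan_cache[key] = plan_dose(itv, spec)
        field = plan_cache[key]
        sampler = ShiftDoseSampler(field, gtv_ref)

        per_curve = []
        for rep in range(replicates):
            seed = base_seed + i * 1000 + rep
            params = motion.scenario_params(row, duration_s=duration_s, seed=seed, index=i)
            trace = motion.simulate_trace(params)
            per_curve.append(
                curve_dose_metrics(
                    trace,
                    sampler,
                    spec,
                    metrics=metrics,
                    dtrue_interval_s=dtrue_interval_s,
                    phase_mode=phase_mode,
                )
            )
        records = build_discrepancy_records(per_curve)
        records.insert(0, "scenario", i)
        all_records.append(records)
        summary = {"scenario": i, **row, "replicates": replicates}
        for x in metrics:
            summary[f"delta_d{x}_pct"] = worst_case_delta(records, x)
        summaries.append(summary)
    return pd.DataFrame(summaries), pd.concat(all_records, ignore_index=True)


# ---------------------------------------------------------------------------
# Trend fitting and paired plan comparison.


@dataclass(frozen=True)
class TrendFit:
    """Ordinary-least-squares linear trend of a sweep."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float


def fit_trend(x, y, predictor: str = "x") -> TrendFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct predictor values")
    res = stats.linregress(x, y)
    return TrendFit(predictor, float(res.slope), float(res.intercept), float(res.rvalue**2))


@dataclass(frozen=True)
class PairedComparison:
    """Per-fraction paired comparison of two plans' Dtrue_99."""

    standard_pct: np.ndarray
    robust_pct: np.ndarray
    mean_difference_pct: float
    t_pvalue: float
    wilcoxon_pvalue: float
    alpha: float = 0.05

    @property
    def significant_t(self) -> bool:
        return self.t_pvalue <= self.alpha

    @property
    def significant_wilcoxon(self) -> bool:
        return self.wilcoxon_pvalue <= self.alpha


def compare_robust(standard_pct, robust_pct, alpha: float = 0.05) -> PairedComparison:
    """Paired two-sided tests of robust vs standard target coverage.

    Both the paired t-test and the Wilcoxon signed-rank test are
    reported (the field tends to quote them interchangeably).  With
    identical inputs (all paired differences zero) both p-values are
    reported as 1.
    """
    standard = np.asarray(standard_pct, dtype=float)
    robust = np.asarray(robust_pct, dtype=float)
    if standard.shape != robust.shape:
        raise ValueError("paired lists must have equal length")
    if standard.size < 2:
        raise ValueError("need at least two paired values")
    diff = robust - standard
    if np.allclose(diff, 0.0):
        t_p = w_p = 1.0
    else:
        t_p = float(stats.ttest_rel(robust, standard).pvalue)
        w_p = float(stats.wilcoxon(robust, standard).pvalue)
        if np.isnan(t_p):  # zero-variance nonzero difference: maximal evidence
            t_p = 0.0
    return PairedComparison(standard, robust, float(diff.mean()), t_p, w_p, alpha)
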