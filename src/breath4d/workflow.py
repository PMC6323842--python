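"""Experiment orchestration: configs, runs, provenance.

Ties the pipeline stages into the three runnable experiments:

* ``simulate``  -- write the scenario bank of breathing-trace CSVs
  with a JSON manifest,
* ``evaluate``  -- run phantom/dose/accumulation/evaluation over the
  bank and write the sweep summary, trend fits and run report,
* ``robust``    -- emulate the fiducial-tracked patients, build
  standard vs pdf-extended robust plans, and write the paired
  comparison.

Every output directory carries a report naming the config hash and all
seeds used, so an archived config reproduces a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, motion, processing
from .dose import PlanSpec, plan_dose, robust_plan_dose
from .evaluate import (
    ShiftDoseSampler,
    compare_robust,
    curve_dose_metrics,
    fit_trend,
    run_sweep,
    traditional_phase_positions,
)
from .phantom import PhantomGrid, TargetGeometry, build_itv, make_gtv_mask

__all__ = [
    "RunConfig",
    "cmd_simulate",
    "cmd_evaluate",
    "cmd_robust",
    "patient_robust_comparison",
    "load_config",
]


@dataclass(frozen=True)
class RunConfig:
    """A fully serializable description of one experiment run."""

    scenarios: tuple[dict, ...] = motion.SCENARIO_GRID
    replicates: int = 10
    duration_s: float = 100.0
    sample_interval_s: float = 0.02
    dtrue_interval_s: float = 0.4
    diameter_cm: float = 3.0
    phase_mode: str = "full"
    base_seed: int = 0
    plan: dict = field(
        default_factory=lambda: dict(
            prescription_gy=60.0,
            n_fractions=5,
            isodose_level=0.8,
            core_depth_mm=5.0,
            penumbra_sigma_mm=3.0,
        )
    )
    phantom: dict = field(default_factory=lambda: dict(shape=(120, 120, 120), voxel_mm=1.0))
    output_dir: str = "runs/default"

    def plan_spec(self) -> PlanSpec:
        return PlanSpec(**self.plan)

    def grid(self) -> PhantomGrid:
        p = dict(self.phantom)
        p["shape"] = tuple(p.get("shape", (120, 120, 120)))
        return PhantomGrid(**p)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = [dict(s) for s in self.scenarios]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "scenarios" in data:
            data["scenarios"] = tuple(dict(s) for s in data["scenarios"])
        if "phantom" in data:
            data["phantom"] = dict(data["phantom"])
            if "shape" in data["phantom"]:
                data["phantom"]["shape"] = tuple(data["phantom"]["shape"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _ensure_outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".writable"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out} is not writable: {exc}") from exc
    return out


def _write_report(out: Path, config: RunConfig, seeds: list[int], extra: dict) -> None:
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "versions": {
            "breath4d": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        **extra,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))


def cmd_simulate(config: RunConfig) -> Path:
    """Write the scenario-bank trace CSVs plus their JSON manifest."""
    out = _ensure_outdir(config)
    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    bank = motion.generate_scenario_bank(
        config.scenarios,
        replicates=config.replicates,
        base_seed=config.base_seed,
        duration_s=config.duration_s,
        sample_interval_s=config.sample_interval_s,
    )
    manifest, seeds = {}, []
    for entry in bank:
        name = f"trace_row{entry['row_index']:02d}_rep{entry['replicate']:02d}.csv"
        motion.write_trace_csv(entry["trace"], traces_dir / name)
        manifest[name] = {
            "row": entry["row"],
            "row_index": entry["row_index"],
            "replicate": entry["replicate"],
            "seed": entry["seed"],
            "config_hash": config.config_hash(),
        }
        seeds.append(entry["seed"])
    (traces_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _write_report(out, config, seeds, {"n_traces": len(bank)})
    return traces_dir


def cmd_evaluate(config: RunConfig) -> pd.DataFrame:
    """Run the full sweep over existing traces and write the outputs.

    Requires ``cmd_simulate`` to have populated the trace directory;
    traces are read back from CSV so the evaluation consumes exactly
    what was archived.
    """
    out = _ensure_outdir(config)
    traces_dir = out / "traces"
    manifest_path = traces_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}; run simulate first")
    manifest = json.loads(manifest_path.read_text())
    for name in manifest:
        if not (traces_dir / name).exists():
            raise FileNotFoundError(f"missing trace file: {traces_dir / name}")

    spec = config.plan_spec()
    grid = config.grid()
    gtv_ref = make_gtv_mask(grid, TargetGeometry(config.diameter_cm, 0))

    # group manifest entries per scenario row
    by_row: dict[int, list] = {}
    for name, meta in manifest.items():
        by_row.setdefault(meta["row_index"], []).append((name, meta))

    plan_cache: dict[tuple, object] = {}
    summaries, seeds = [], []
    from .evaluate import build_discrepancy_records, worst_case_delta

    for row_index in sorted(by_row):
        entries = sorted(by_row[row_index], key=lambda nm: nm[1]["replicate"])
        row = entries[0][1]["row"]
        positions = traditional_phase_positions(
            row["mean_excursion_mm"], phase_mode=config.phase_mode
        )
        key = tuple(positions)
        if key not in plan_cache:
            plan_cache[key] = plan_dose(build_itv(grid, config.diameter_cm, positions), spec)
        sampler = ShiftDoseSampler(plan_cache[key], gtv_ref)
        per_curve = []
        for name, meta in entries:
            trace = motion.read_trace_csv(traces_dir / name)
            seeds.append(meta["seed"])
            per_curve.append(
                curve_dose_metrics(
                    trace,
                    sampler,
                    spec,
                    dtrue_interval_s=config.dtrue_interval_s,
                    phase_mode=config.phase_mode,
                )
            )
        records = build_discrepancy_records(per_curve)
        summary = {"scenario": row_index, **row, "replicates": len(entries)}
        for x in (99, 95):
            summary[f"delta_d{x}_pct"] = worst_case_delta(records, x)
        summaries.append(summary)

    summary_df = pd.DataFrame(summaries)
    summary_df.to_csv(out / "sweep_summary.csv", index=False)

    trends = {}
    for predictor in ("mean_excursion_mm", "excursion_cv", "mean_period_s", "period_cv"):
        sub = summary_df[
            summary_df.drop(columns=["scenario", predictor, "delta_d99_pct", "delta_d95_pct", "replicates"])
            .apply(lambda c: c == c.mode().iloc[0])
            .all(axis=1)
        ]
        if sub[predictor].nunique() >= 2:
            fit = fit_trend(sub[predictor], sub["delta_d99_pct"], predictor)
            trends[predictor] = asdict(fit)
    (out / "trend_fits.json").write_text(json.dumps(trends, indent=2))
    _write_report(out, config, seeds, {"n_scenarios": len(summaries)})
    return summary_df


# ---------------------------------------------------------------------------
# Patient-like robust-strategy validation.


def patient_robust_comparison(
    fraction_rows,
    *,
    noise_sd_mm: float = 0.5,
    sample_rate_hz: float = 30.0,
    duration_s: float = 100.0,
    filter_cutoff_hz: float = 1.0,
    coverage: float = 0.8,
    diameter_cm: float = 3.0,
    spec: PlanSpec | None = None,
    grid: PhantomGrid | None = None,
    base_seed: int = 0,
) -> dict:
    """Standard vs pdf-extended robust plan on one emulated patient.

    Per fraction a fiducial-like noisy trace is generated from the
    printed per-fraction motion statistics and low-pass filtered.  The
    standard plan is built on a homogeneous planning curve whose
    amplitude is the patient's mean excursion; the robust plan extends
    the phase-position set with every integer mm of the pooled 80%
    position-probability interval.  Each fraction's Dtrue_99 is then
    evaluated under both plans and compared with paired tests.
    """
    spec = spec or PlanSpec()
    grid = grid or PhantomGrid()
    gtv_ref = make_gtv_mask(grid, TargetGeometry(diameter_cm, 0))

    traces, seeds = [], []
    for f, row in enumerate(fraction_rows):
        seed = base_seed + f
        seeds.append(seed)
        params = motion.PatientLikeParams(
            motion=motion.scenario_params(row, duration_s=duration_s, seed=seed),
            noise_sd_mm=noise_sd_mm,
            sample_rate_hz=sample_rate_hz,
        )
        raw = motion.generate_patient_like_trace(params)
        traces.append(processing.lowpass_filter(raw, filter_cutoff_hz))

    planning_amplitude = float(np.mean([r["mean_excursion_mm"] for r in fraction_rows]))
    positions = traditional_phase_positions(planning_amplitude)
    std_field = plan_dose(build_itv(grid, diameter_cm, positions), spec)

    pooled = np.concatenate([t.displacement_mm for t in traces])
    pooled_trace = motion.BreathingTrace(
        np.arange(pooled.size) / sample_rate_hz, pooled, 1.0 / sample_rate_hz
    )
    pdf = processing.empirical_position_pdf(pooled_trace)
    interval = processing.coverage_interval(pdf, coverage)
    rob_field, extended = robust_plan_dose(positions, interval, diameter_cm, grid, spec)

    std_sampler = ShiftDoseSampler(std_field, gtv_ref)
    rob_sampler = ShiftDoseSampler(rob_field, gtv_ref)
    std_d99, rob_d99 = [], []
    for trace in traces:
        for sampler, store in ((std_sampler, std_d99), (rob_sampler, rob_d99)):
            m = curve_dose_metrics(trace, sampler, spec, metrics=(99,))
            store.append(m["dtrue"][99])

    comparison = compare_robust(std_d99, rob_d99)
    return {
        "comparison": comparison,
        "standard_positions_mm": [int(p) for p in positions],
        "extended_positions_mm": extended,
        "coverage_interval_mm": interval,
        "planning_amplitude_mm": planning_amplitude,
        "seeds": seeds,
    }


def cmd_robust(config: RunConfig, patients=(1, 2, 3)) -> dict:
    """Run the robust-strategy validation for the reference patients."""
    out = _ensure_outdir(config)
    results, seeds = {}, []
    for p in patients:
        rows = motion.PATIENT_MOTION_CHARACTERISTICS[p]
        res = patient_robust_comparison(
            rows,
            diameter_cm=config.diameter_cm,
            spec=config.plan_spec(),
            grid=config.grid(),
            base_seed=config.base_seed + 100_000 * p,
            duration_s=config.duration_s,
        )
        seeds.extend(res["seeds"])
        comp = res["comparison"]
        results[str(p)] = {
            "mean_improvement_pct": comp.mean_difference_pct,
            "t_pvalue": comp.t_pvalue,
            "wilcoxon_pvalue": comp.wilcoxon_pvalue,
            "standard_d99_pct": list(comp.standard_pct),
            "robust_d99_pct": list(comp.robust_pct),
            "standard_positions_mm": res["standard_positions_mm"],
            "extended_positions_mm": res["extended_positions_mm"],
            "coverage_interval_mm": list(res["coverage_interval_mm"]),
        }
    (out / "robust_comparison.json").write_text(json.dumps(results, indent=2))
    _write_report(out, config, seeds, {"patients": list(patients)})
    return results
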