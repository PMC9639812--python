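"""Table I/O, run configuration and the end-to-end pipeline.

All tables are long-format UTF-8 CSV with a header row and "." decimals;
time is integer minutes in OD files and hours internally.  The pipeline is
fully reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .competition import (
    CompetitionModel,
    Competitor,
)
from .containers import CompoundRecord, FlowSample, ODTrace
from .curves import classify_delay, measure_tau
from .death import compare_estimates, dyed_fraction, estimate_death_from_curve
from .dose import DoseResponseModel
from .params import DEFAULT_GROWTH, HICA, MVA_2K3, Condition, GrowthParams, ToxinResponse
from .popdyn import default_secretion, simulate_culture
from .screen import candidate_filter, venn_partition
from .synth import (
    DEFAULT_HORIZON,
    DEFAULT_NOISE_SD,
    generate_cm_series,
    generate_compound_table,
    generate_dose_panel,
    generate_flow_counts,
    generate_od_trace,
)

__all__ = [
    "ParseError",
    "read_od_table",
    "write_od_table",
    "read_flow_table",
    "write_flow_table",
    "read_compound_table",
    "write_compound_table",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("odelay")

OD_PRECISION = 6  # decimals kept when writing OD tables


class ParseError(ValueError):
    """Structured table-validation failure, naming the offending rows."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")


def read_od_table(path) -> list[ODTrace]:
    """Read a long-format OD table into one ODTrace per sample_id.

    Required columns: sample_id, time_min, od.  Optional metadata columns
    (medium, strain, dose_mM, preculture, ...) are carried through.  Rows
    are sorted by time on load; negative OD, non-numeric values and
    duplicate times are reported with their (1-based, header-exclusive)
    row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "time_min", "od"], path)
    df["_row"] = np.arange(1, len(df) + 1)
    for col in ("time_min", "od"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[coerced.isna() & df[col].notna(), "_row"].tolist()
        bad += df.loc[df[col].isna(), "_row"].tolist()
        if bad:
            raise ParseError(f"{path}: non-numeric {col!r} in rows {sorted(bad)}")
        df[col] = coerced
    neg = df.loc[df["od"] < 0, "_row"].tolist()
    if neg:
        raise ParseError(f"{path}: negative OD in rows {neg}")
    meta_cols = [
        c for c in df.columns if c not in ("sample_id", "time_min", "od", "_row")
    ]
    traces = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_min")
        dup = grp.loc[grp["time_min"].duplicated(), "_row"].tolist()
        if dup:
            raise ParseError(
                f"{path}: duplicate time points for sample {sid!r} in rows {dup}"
            )
        metadata = {c: grp[c].iloc[0] for c in meta_cols}
        traces.append(
            ODTrace(
                sample_id=str(sid),
                times_min=grp["time_min"].to_numpy(),
                od=grp["od"].to_numpy(),
                metadata=metadata,
            )
        )
    return traces


def write_od_table(traces: list[ODTrace], path) -> Path:
    path = Path(path)
    df = pd.concat([tr.to_frame() for tr in traces], ignore_index=True)
    df["od"] = df["od"].round(OD_PRECISION)
    df.to_csv(path, index=False)
    return path


def write_flow_table(samples: list[FlowSample], path) -> Path:
    path = Path(path)
    rows = [
        {"sample_id": s.sample_id, "t_h": s.t, "gate": gate, "count": c}
        for s in samples
        for gate, c in s.counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_flow_table(path) -> list[FlowSample]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "t_h", "gate", "count"], path)
    samples = []
    for (sid, t), grp in df.groupby(["sample_id", "t_h"], sort=False):
        samples.append(
            FlowSample(
                sample_id=str(sid),
                t=float(t),
                counts=dict(zip(grp["gate"], grp["count"].astype(int))),
            )
        )
    return samples


_FLAG_COLS = [
    "in_mm",
    "in_wt_cm",
    "in_fbp1_cm",
    "changes_postdelay_growth",
    "affects_growth_with_glucose",
    "delays_adapted_cells",
]


def write_compound_table(records: list[CompoundRecord], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"compound": r.compound, **{c: getattr(r, c) for c in _FLAG_COLS}} for r in records]
    ).to_csv(path, index=False)
    return path


def read_compound_table(path) -> list[CompoundRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["compound", "in_mm", "in_wt_cm", "in_fbp1_cm"], path)
    records = []
    for _, row in df.iterrows():
        kw = {}
        for c in _FLAG_COLS:
            if c in df.columns and not pd.isna(row[c]):
                kw[c] = bool(row[c])
        records.append(CompoundRecord(compound=str(row["compound"]), **kw))
    return records


class GrowthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r: float = DEFAULT_GROWTH.r
    lag: float = 0.0
    K: float = 1.0
    a0: float = 0.005

    def to_params(self) -> GrowthParams:
        return GrowthParams(r=self.r, lag=self.lag, K=self.K, a0=self.a0)


class ScreenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_shared: int = 20
    n_also_in_mm: int = 8
    n_noncm: int = 5
    n_pass: int = 2


class PipelineConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected up front."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    outdir: str = "odelay_run"
    noise_sd: float = DEFAULT_NOISE_SD
    horizon: float = DEFAULT_HORIZON
    growth: GrowthConfig = GrowthConfig()
    dose_grid_max: float = 40.0
    dose_grid_step: float = 2.5
    incubation_times: list[float] = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0]
    competition_events: int = 500_000
    viability_events: int = 100_000
    screen: ScreenConfig = ScreenConfig()
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return None if math.isnan(obj) else round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate -> analyse -> infer -> report, end to end.

    Writes all intermediate tables under ``config.outdir`` plus a JSON
    summary of tau, r, d_hat, c_crit_hat and f_inf, with a machine-readable
    self-check section.  Byte-identical output for identical (config, seed).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.growth.to_params()
    sp = default_secretion(p)
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]
    summary: dict = {"seed": config.seed}

    # -- stage 1: baseline growth in fresh glucose-free medium ------------
    baseline_trace = generate_od_trace(
        p, Condition(medium_label="0% MM"), HICA, config.horizon,
        config.noise_sd, seeds[0], sample_id="baseline",
    )
    baseline = measure_tau(baseline_trace)
    summary["baseline"] = {
        "a0": baseline.a0,
        "tau_h": baseline.tau,
        "r_hat": baseline.r_hat,
        "doubling_time_h": baseline.doubling_time,
    }
    log.info("stage=baseline tau=%.2fh r=%.4f out=%s", baseline.tau,
             baseline.r_hat or float("nan"), outdir / "baseline.csv")

    # -- stage 2: conditioned-medium incubation series ---------------------
    cm_traces = generate_cm_series(
        config.incubation_times, sp, p, seeds[1], noise_sd=config.noise_sd,
        horizon=config.horizon,
    )
    write_od_table([baseline_trace, *cm_traces], outdir / "od_traces.csv")
    cm_rows = []
    for t_inc, trace in zip(config.incubation_times, cm_traces):
        res = measure_tau(trace, estimate_rate=False)
        classify_delay(res, baseline.tau)
        d_est = estimate_death_from_curve(res.tau, p.r, p.lag)
        cm_rows.append(
            {
                "incubation_h": t_inc,
                "tau_h": res.tau,
                "tau_method": res.tau_method,
                "delay_present": res.delay_present,
                "d_hat": d_est.d_hat,
            }
        )
    pd.DataFrame(cm_rows).to_csv(outdir / "cm_series.csv", index=False)
    inducing = [row["incubation_h"] for row in cm_rows if row["delay_present"]]
    summary["cm_series"] = {
        "rows": cm_rows,
        "min_delay_inducing_incubation_h": min(inducing) if inducing else None,
    }
    log.info("stage=cm_series inducing=%s", inducing)

    # -- stage 3: dose-response panels ------------------------------------
    doses = np.arange(0.0, config.dose_grid_max + 1e-9, config.dose_grid_step)
    summary["dose_response"] = {}
    for name, toxin, seed in (("HICA", HICA, seeds[2]), ("2K3MVA", MVA_2K3, seeds[3])):
        traces = generate_dose_panel(
            doses.tolist(), toxin, p, seed, noise_sd=config.noise_sd,
            horizon=config.horizon,
        )
        res = DoseResponseModel.from_traces(traces).fit()
        summary["dose_response"][name] = {
            "c_crit_hat_mM": res.c_crit_hat,
            "monotone_ok": res.monotone_ok,
            "effect_threshold_mM": res.effect_threshold,
        }
        log.info("stage=dose toxin=%s c_crit=%.1f", name, res.c_crit_hat)

    # -- stage 4: viability staining vs curve inversion --------------------
    kill = 0.9  # near-critical dose
    traj = simulate_culture(p, kill, horizon=8.0)
    state = traj.state_at(8.0)
    flow = generate_flow_counts(
        {"cells": state}, config.viability_events, count_dead=True,
        seed=seeds[4], sample_id="viability_8h",
    )
    write_flow_table([flow], outdir / "viability_flow.csv")
    stained = dyed_fraction(flow)
    kill_trace = generate_od_trace(
        p, Condition(effective_dose=28.0, medium_label="0% MM + 28 mM"),
        HICA, config.horizon, config.noise_sd, seeds[4],
        sample_id="near_critical",
    )
    kc = measure_tau(kill_trace, estimate_rate=False)
    curve_est = estimate_death_from_curve(kc.tau, p.r, p.lag)
    from .death import DeathEstimate

    comp = compare_estimates(
        curve_est, DeathEstimate(d_hat=stained, source="flow_staining", tau_used=8.0)
    )
    summary["death_inference"] = {
        "dyed_fraction_8h": stained,
        "curve_d_hat": curve_est.d_hat,
        "delta": comp.delta,
        "agree_within_0.1": comp.agree,
    }
    log.info("stage=death dyed=%.3f curve=%.3f", stained, curve_est.d_hat)

    # -- stage 5: competition adapted vs unadapted -------------------------
    adapted = Competitor(p, kill_fraction=0.0, label="green")
    unadapted = Competitor(p, kill_fraction=2.0 / 3.0, label="red")
    model = CompetitionModel(adapted, unadapted, (1.0, 1.0), horizon=72.0)
    pred = model.fit().prediction
    rng = np.random.default_rng(seeds[5])
    flow_samples = []
    for i, t_obs in enumerate(np.arange(0.0, 72.1, 12.0)):
        j = int(np.argmin(np.abs(pred.t - t_obs)))
        states = {
            "green": _state(pred.trajectory_a[j], 0.0, t_obs),
            "red": _state(pred.trajectory_b[j], 0.0, t_obs),
        }
        flow_samples.append(
            generate_flow_counts(
                states, config.competition_events, count_dead=False,
                seed=rng, sample_id=f"compete_{i}",
            )
        )
    write_flow_table(flow_samples, outdir / "competition_flow.csv")
    fit = model.fit(flow_samples)
    summary["competition"] = {
        "f_inf": fit.f_inf,
        "t_ss_h": fit.t_ss,
        "max_abs_deviation": fit.report.max_abs_deviation,
        "agree": fit.report.agree,
    }
    log.info("stage=competition f_inf=%.3f agree=%s", fit.f_inf, fit.report.agree)

    # -- stage 6: inhibitor screen -----------------------------------------
    records = generate_compound_table(
        config.screen.n_shared, config.screen.n_also_in_mm,
        config.screen.n_noncm, seed=config.seed, n_pass=config.screen.n_pass,
    )
    write_compound_table(records, outdir / "compounds.csv")
    part = venn_partition(records)
    by_name = {r.compound: r for r in records}
    hits = candidate_filter([by_name[n] for n in part.candidate_region])
    summary["screen"] = {
        "region_counts": part.counts,
        "candidate_region_size": len(part.candidate_region),
        "n_hits": len(hits),
        "hits": [r.compound for r in hits],
    }
    log.info("stage=screen candidates=%d hits=%d",
             len(part.candidate_region), len(hits))

    # -- self-check ---------------------------------------------------------
    dt = summary["baseline"]["doubling_time_h"]
    summary["self_check"] = {
        "doubling_time_within_2pct": dt is not None and abs(dt - 10.0) / 10.0 <= 0.02,
        # single-trace check: ~3 sigma of per-trace tau noise at default
        # settings (the 20-seed average sits within 15%)
        "cm30_tau_within_25pct": abs(cm_rows[-1]["tau_h"] - 20.0) / 20.0 <= 0.25,
        "hica_c_crit_is_30": summary["dose_response"]["HICA"]["c_crit_hat_mM"] == 30.0,
        "mva_c_crit_is_25": summary["dose_response"]["2K3MVA"]["c_crit_hat_mM"] == 25.0,
        "dyed_fraction_ge_0.8": stained >= 0.8,
        "min_inducing_incubation_ge_15": bool(inducing) and min(inducing) >= 15.0,
        "competition_agrees": fit.report.agree,
        "candidate_region_matches": len(part.candidate_region)
        == config.screen.n_shared - config.screen.n_also_in_mm,
    }
    summary = _round_floats(_jsonable(summary))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    return summary


def _state(living, dead, t):
    from .params import CultureState

    return CultureState(living=float(living), dead=float(dead), t=float(t))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "censored"
    return obj
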