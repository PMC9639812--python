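"""Delay-phase and growth-rate estimation from OD traces.

The delay statistic tau is the time at which the observed OD reaches twice
its initial value a0.  When a trace reaches 1.5*a0 but never doubles within
the observation window, tau is extrapolated as t_{1.5} * ln2/ln1.5 (exact
for exponential growth); when not even 1.5*a0 is reached, tau is censored.

``GrowthCurveModel`` wraps the functional estimators in a model/results
pair: build it from a trace (or DataFrame), call ``fit()``, and read the
estimates off the returned ``GrowthCurveResults``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ODTrace
from .params import LN2

__all__ = [
    "DelayResult",
    "moving_average",
    "estimate_a0",
    "estimate_growth_rate",
    "measure_tau",
    "classify_delay",
    "GrowthCurveModel",
    "GrowthCurveResults",
]

# Analysis conventions (the instrument protocol does not fix these):
# a 61-min centred moving average to tame 1-min turbidimeter noise, a
# 90-min linear-fit baseline for a0, a 30-min sustained-crossing rule for
# tau, a minimum 5-h steady-growth band with an R^2 floor for the growth
# rate, and a 5-h margin over baseline tau for delay classification.
DEFAULT_SMOOTH_MIN = 61
DEFAULT_BASELINE_MIN = 90
DEFAULT_SUSTAIN_MIN = 30
DEFAULT_FIT_WINDOW_H = 5.0
DEFAULT_R2_MIN = 0.98
DEFAULT_MARGIN_H = 5.0


@dataclass
class DelayResult:
    """Per-trace delay-phase analysis output.

    ``tau`` is in hours, ``inf`` when censored; ``tau_method`` is one of
    ``direct``, ``extrapolated_1p5`` or ``censored``.
    """

    a0: float
    tau: float
    tau_method: str
    r_hat: float | None = None
    delay_present: bool | None = None
    baseline_tau: float | None = None
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def censored(self) -> bool:
        return math.isinf(self.tau)

    @property
    def doubling_time(self) -> float | None:
        return LN2 / self.r_hat if self.r_hat else None


def moving_average(trace: ODTrace, window: int = DEFAULT_SMOOTH_MIN) -> ODTrace:
    """Centred moving average over ``window`` minutes; edges shrink.

    The window must convert to an odd number of samples and may not exceed
    the trace length.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1 minute, got {window}")
    n = max(1, int(round(window / trace.dt_min)))
    if n > len(trace):
        raise ValueError(
            f"window of {n} samples exceeds trace length {len(trace)}"
        )
    if n % 2 == 0:
        raise ValueError(f"window must span an odd number of samples, got {n}")
    if n == 1:
        return trace.replace_od(trace.od.copy())
    sm = pd.Series(trace.od).rolling(n, center=True, min_periods=1).mean()
    return trace.replace_od(sm.to_numpy())


def estimate_a0(trace: ODTrace, baseline_min: int = DEFAULT_BASELINE_MIN) -> float:
    """Initial OD a0: intercept of a least-squares line over the baseline window.

    The line intercept at t=0 is unbiased to first order in the early growth
    (curvature enters only at second order), unlike the window mean.
    """
    mask = trace.times_min <= baseline_min
    if mask.sum() < 2:
        mask = np.zeros(len(trace), dtype=bool)
        mask[: min(2, len(trace))] = True
    t = trace.times_min[mask]
    y = trace.od[mask]
    slope, intercept = np.polyfit(t, y, 1)
    a0 = float(intercept)
    if a0 <= 0:
        raise ValueError(f"non-positive baseline a0 ({a0:.4g}) in {trace.sample_id!r}")
    return a0


def estimate_growth_rate(
    trace: ODTrace,
    fit_window: float = DEFAULT_FIT_WINDOW_H,
    K: float | None = 1.0,
    *,
    smooth_window: int = DEFAULT_SMOOTH_MIN,
    baseline_min: int = DEFAULT_BASELINE_MIN,
    r2_min: float = DEFAULT_R2_MIN,
    lower_frac: float = 1.5,
    upper_frac: float = 0.7,
) -> float:
    """Steady-growth-phase rate r (1/h) by a log-linear band fit.

    A straight line is fitted by least squares to the log of the smoothed
    OD over the steady-growth band ``lower_frac * a0 <= OD <= upper_frac *
    plateau``.  When the carrying cap ``K`` of the culture is known
    (default 1.0 OD, the instrument-culture cap), the logit
    ``ln(OD/(K-OD))`` is fitted instead, which linearises logistic growth
    exactly and removes the crowding bias of a plain log fit; pass
    ``K=None`` for a pure log-linear fit (exact on exponential traces).
    The band must span at least ``fit_window`` hours and the fit must
    explain at least ``r2_min`` of the variance.
    """
    sm = moving_average(trace, smooth_window) if smooth_window > 1 else trace
    a0 = estimate_a0(trace, baseline_min)
    t = sm.t_hours
    od = sm.od
    plateau = upper_frac * (K if K is not None else float(od.max()))
    mask = (od >= lower_frac * a0) & (od <= plateau) & (od > 0)
    if K is not None:
        mask &= od < 0.999 * K
    if mask.sum() < 3 or t[mask].max() - t[mask].min() < fit_window:
        raise ValueError(f"no steady growth phase found in {trace.sample_id!r}")
    y = np.log(od[mask] / (K - od[mask])) if K is not None else np.log(od[mask])
    tm = t[mask]
    tc = tm - tm.mean()
    yc = y - y.mean()
    stt = float(tc @ tc)
    syy = float(yc @ yc)
    sty = float(tc @ yc)
    slope = sty / stt
    r2 = sty * sty / (stt * syy) if syy > 0 else 0.0
    if r2 < r2_min:
        raise ValueError(
            f"growth-band fit below the quality floor R^2 >= {r2_min} "
            f"in {trace.sample_id!r}"
        )
    return slope


def _first_sustained_crossing(
    t_h: np.ndarray, od: np.ndarray, threshold: float, sustain_samples: int
) -> float | None:
    """First time OD >= threshold and stays there for ``sustain_samples``."""
    above = od >= threshold
    if sustain_samples <= 1:
        idx = np.flatnonzero(above)
        return float(t_h[idx[0]]) if idx.size else None
    from numpy.lib.stride_tricks import sliding_window_view

    if len(above) < sustain_samples:
        return None
    runs = sliding_window_view(above, sustain_samples).all(axis=1)
    idx = np.flatnonzero(runs)
    return float(t_h[idx[0]]) if idx.size else None


def measure_tau(
    trace: ODTrace,
    *,
    smooth_window: int = DEFAULT_SMOOTH_MIN,
    baseline_min: int = DEFAULT_BASELINE_MIN,
    sustain_min: int = DEFAULT_SUSTAIN_MIN,
    estimate_rate: bool = True,
) -> DelayResult:
    """Measure the delay statistic tau on one trace.

    tau is the first time the smoothed OD reaches 2*a0 and stays there for
    ``sustain_min`` minutes.  If the trace reaches 1.5*a0 but never 2*a0,
    tau is extrapolated by the factor ln2/ln1.5; otherwise it is censored
    (``tau = inf``).
    """
    if len(trace) < 2 or trace.times_min[-1] - trace.times_min[0] < 60.0:
        raise ValueError("trace must span at least 1 h")
    a0 = estimate_a0(trace, baseline_min)
    sm = moving_average(trace, smooth_window) if smooth_window > 1 else trace
    sustain = max(1, int(round(sustain_min / trace.dt_min)) + 1)
    t_h = sm.t_hours
    tau2 = _first_sustained_crossing(t_h, sm.od, 2.0 * a0, sustain)
    if tau2 is not None:
        tau, method = tau2, "direct"
    else:
        tau15 = _first_sustained_crossing(t_h, sm.od, 1.5 * a0, sustain)
        if tau15 is not None:
            tau, method = tau15 * LN2 / math.log(1.5), "extrapolated_1p5"
        else:
            tau, method = math.inf, "censored"
    r_hat = None
    if estimate_rate:
        try:
            r_hat = estimate_growth_rate(
                trace, smooth_window=smooth_window, baseline_min=baseline_min
            )
        except ValueError:
            r_hat = None
    return DelayResult(
        a0=a0,
        tau=tau,
        tau_method=method,
        r_hat=r_hat,
        sample_id=trace.sample_id,
        metadata=dict(trace.metadata),
    )


def classify_delay(
    result: DelayResult, baseline_tau: float, margin: float = DEFAULT_MARGIN_H
) -> bool:
    """Flag a delay phase: tau censored or exceeding baseline tau + margin.

    Mutates ``result`` in place (sets ``delay_present`` and
    ``baseline_tau``) and returns the flag.
    """
    if not baseline_tau > 0:
        raise ValueError(f"baseline_tau must be positive, got {baseline_tau}")
    flag = result.censored or result.tau > baseline_tau + margin
    result.delay_present = flag
    result.baseline_tau = baseline_tau
    return flag


class GrowthCurveModel:
    """Delay-phase model of a single OD trace.

    Statsmodels-style entry point: construct from an :class:`ODTrace` (or a
    long-format DataFrame with ``time_min``/``od`` columns), then ``fit()``.
    """

    def __init__(
        self,
        trace: ODTrace,
        *,
        smooth_window: int = DEFAULT_SMOOTH_MIN,
        baseline_min: int = DEFAULT_BASELINE_MIN,
        sustain_min: int = DEFAULT_SUSTAIN_MIN,
        fit_window: float = DEFAULT_FIT_WINDOW_H,
        r2_min: float = DEFAULT_R2_MIN,
    ) -> None:
        self.trace = trace
        self.smooth_window = smooth_window
        self.baseline_min = baseline_min
        self.sustain_min = sustain_min
        self.fit_window = fit_window
        self.r2_min = r2_min

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str | None = None, **kw):
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        elif "sample_id" in df.columns:
            ids = df["sample_id"].unique()
            if len(ids) != 1:
                raise ValueError(
                    f"DataFrame holds {len(ids)} samples; pass sample_id"
                )
            sample_id = ids[0]
        df = df.sort_values("time_min")
        trace = ODTrace(
            sample_id=str(sample_id or "trace"),
            times_min=df["time_min"].to_numpy(),
            od=df["od"].to_numpy(),
        )
        return cls(trace, **kw)

    def fit(
        self, baseline_tau: float | None = None, margin: float = DEFAULT_MARGIN_H
    ) -> "GrowthCurveResults":
        res = measure_tau(
            self.trace,
            smooth_window=self.smooth_window,
            baseline_min=self.baseline_min,
            sustain_min=self.sustain_min,
        )
        if baseline_tau is not None:
            classify_delay(res, baseline_tau, margin)
        return GrowthCurveResults(self, res)


class GrowthCurveResults:
    """Estimates from one fitted growth curve."""

    def __init__(self, model: GrowthCurveModel, delay: DelayResult) -> None:
        self.model = model
        self.delay = delay

    a0 = property(lambda self: self.delay.a0)
    tau = property(lambda self: self.delay.tau)
    tau_method = property(lambda self: self.delay.tau_method)
    r_hat = property(lambda self: self.delay.r_hat)
    doubling_time = property(lambda self: self.delay.doubling_time)
    delay_present = property(lambda self: self.delay.delay_present)

    def summary(self) -> str:
        d = self.delay
        tau = "censored" if d.censored else f"{d.tau:10.3f}"
        rows = [
            ("sample", d.sample_id or self.model.trace.sample_id),
            ("a0 (OD)", f"{d.a0:10.5f}"),
            ("tau (h)", tau),
            ("tau method", d.tau_method),
            ("r_hat (1/h)", "n/a" if d.r_hat is None else f"{d.r_hat:10.5f}"),
            (
                "doubling time (h)",
                "n/a" if d.r_hat is None else f"{LN2 / d.r_hat:10.3f}",
            ),
            (
                "delay present",
                "n/a" if d.delay_present is None else str(d.delay_present),
            ),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Growth curve delay-phase analysis", "=" * 40]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)
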