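"""Two-label competition in conditioned medium: prediction and measurement.

Both subpopulations share one culture (and one carrying cap); each may lose
a fraction of its inoculum to the toxin at t=0 and may carry a lag.  For
equal growth rates the steady-state living-cell fraction has the closed
form f_inf = w_A/(w_A + w_B) with w_X = N_X0 (1-d_X) e^{-r lag_X}: the
dead mass and shared logistic crowding slow both populations identically,
so the survivor ratio set just after the lags persists.  Unequal rates make
the limit degenerate (0 or 1) and the transient trajectory is what matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FlowSample
from .params import GrowthParams

__all__ = [
    "Competitor",
    "CompetitionPrediction",
    "predict_steady_state",
    "fraction_timecourse",
    "compare_prediction",
    "CompetitionModel",
    "plot_fractions",
]


@dataclass(frozen=True)
class Competitor:
    """One labelled subpopulation: growth parameters plus its kill fraction."""

    growth: GrowthParams
    kill_fraction: float = 0.0
    label: str = "A"

    def __post_init__(self) -> None:
        if not (0.0 <= self.kill_fraction <= 1.0):
            raise ValueError("kill_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CompetitionPrediction:
    """Predicted fraction dynamics of competitor A."""

    f_inf: float
    t: np.ndarray  # h
    f_t: np.ndarray  # living-cell fraction of A
    t_ss: float  # first t with |f_t - f_inf| < 0.01; nan if never
    degenerate: bool  # unequal growth rates: f_inf is 0 or 1
    trajectory_a: np.ndarray
    trajectory_b: np.ndarray
    dead_a: float
    dead_b: float


def _simulate_pair(
    a: Competitor,
    b: Competitor,
    n_a0: float,
    n_b0: float,
    K: float,
    horizon: float,
    step: float,
):
    """Fixed-step RK4 for two logistic competitors with inert dead mass.

    Lag boundaries are inserted into the time grid so the piecewise
    dynamics are integrated exactly up to RK4 accuracy.
    """
    dead = n_a0 * a.kill_fraction + n_b0 * b.kill_fraction
    la0 = n_a0 * (1.0 - a.kill_fraction)
    lb0 = n_b0 * (1.0 - b.kill_fraction)
    grid = np.arange(0.0, horizon + step / 2, step)
    for lam in (a.growth.lag, b.growth.lag):
        if 0.0 < lam < horizon and not np.any(np.isclose(grid, lam)):
            grid = np.sort(np.append(grid, lam))
    la = np.empty_like(grid)
    lb = np.empty_like(grid)
    la[0], lb[0] = la0, lb0

    def rhs(t, ya, yb):
        crowd = 1.0 - (ya + yb + dead) / K
        da = a.growth.r * ya * crowd if t >= a.growth.lag else 0.0
        db = b.growth.r * yb * crowd if t >= b.growth.lag else 0.0
        return da, db

    for i in range(len(grid) - 1):
        h = grid[i + 1] - grid[i]
        t0, ya, yb = grid[i], la[i], lb[i]
        k1a, k1b = rhs(t0, ya, yb)
        k2a, k2b = rhs(t0 + h / 2, ya + h / 2 * k1a, yb + h / 2 * k1b)
        k3a, k3b = rhs(t0 + h / 2, ya + h / 2 * k2a, yb + h / 2 * k2b)
        k4a, k4b = rhs(t0 + h, ya + h * k3a, yb + h * k3b)
        la[i + 1] = ya + h / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
        lb[i + 1] = yb + h / 6 * (k1b + 2 * k2b + 2 * k3b + k4b)
    return grid, la, lb, n_a0 * a.kill_fraction, n_b0 * b.kill_fraction


def predict_steady_state(
    comp_a: Competitor,
    comp_b: Competitor,
    inoculum_ratio: tuple[float, float] = (1.0, 1.0),
    *,
    horizon: float = 200.0,
    step: float = 0.05,
    count_dead: bool = False,
) -> CompetitionPrediction:
    """Forward-simulate both subpopulations and predict the steady state.

    The inoculum of each competitor is its ``growth.a0`` scaled by its
    normalised ratio weight.  For equal growth rates the closed-form
    ``f_inf`` is used (and the simulation must agree with it); unequal
    rates give a degenerate limit of 0 or 1, flagged as such.  By default
    fractions count living cells only.
    """
    wa, wb = inoculum_ratio
    if wa < 0 or wb < 0 or wa + wb == 0:
        raise ValueError(f"invalid inoculum ratio {inoculum_ratio}")
    if not math.isclose(comp_a.growth.K, comp_b.growth.K):
        raise ValueError("competitors must share one carrying cap K")
    n_a0 = comp_a.growth.a0 * wa / (wa + wb)
    n_b0 = comp_b.growth.a0 * wb / (wa + wb)
    K = comp_a.growth.K
    t, la, lb, dead_a, dead_b = _simulate_pair(
        comp_a, comp_b, n_a0, n_b0, K, horizon, step
    )
    num = la + (dead_a if count_dead else 0.0)
    den = la + lb + ((dead_a + dead_b) if count_dead else 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_t = np.where(den > 0, num / den, 0.5)

    ra, rb = comp_a.growth.r, comp_b.growth.r
    degenerate = not math.isclose(ra, rb, rel_tol=1e-9)
    u_a = n_a0 * (1.0 - comp_a.kill_fraction) * math.exp(-ra * comp_a.growth.lag)
    u_b = n_b0 * (1.0 - comp_b.kill_fraction) * math.exp(-rb * comp_b.growth.lag)
    if u_a == 0.0 and u_b == 0.0:
        f_inf = 0.5 if not count_dead else (
            dead_a / (dead_a + dead_b) if dead_a + dead_b > 0 else 0.5
        )
    elif degenerate:
        if u_a == 0.0:
            f_inf = 0.0
        elif u_b == 0.0:
            f_inf = 1.0
        else:
            f_inf = 1.0 if ra > rb else 0.0
        if count_dead:
            f_inf = float(f_t[-1])  # dead mass keeps the limit interior
    else:
        f_inf = u_a / (u_a + u_b)
        if count_dead:
            live = la[-1] + lb[-1]
            f_inf = (f_inf * live + dead_a) / (live + dead_a + dead_b)
    close = np.abs(f_t - f_inf) < 0.01
    t_ss = float(t[np.argmax(close)]) if close.any() else math.nan
    return CompetitionPrediction(
        f_inf=float(f_inf),
        t=t,
        f_t=f_t,
        t_ss=t_ss,
        degenerate=degenerate,
        trajectory_a=la,
        trajectory_b=lb,
        dead_a=dead_a,
        dead_b=dead_b,
    )


def fraction_timecourse(
    samples: list[FlowSample],
    label: str,
    *,
    include_dead: bool = False,
) -> pd.DataFrame:
    """Per-time fraction of one label with binomial standard errors.

    Gates are parsed as ``<label>_<viability>``; by default only ``_live``
    gates are counted (dead cells are assumed to drop out of the label
    gates), ``include_dead`` adds the ``_dead`` gates of each label.
    """
    if not samples:
        raise ValueError("need at least one flow sample")
    rows = []
    for s in sorted(samples, key=lambda s: s.t):
        total = 0
        hit = 0
        for gate, c in s.counts.items():
            base, _, viab = gate.rpartition("_")
            if viab == "dead" and not include_dead:
                continue
            total += c
            if base == label:
                hit += c
        if total == 0:
            raise ValueError(f"sample {s.sample_id!r} has zero counted events")
        f = hit / total
        rows.append(
            {
                "t": s.t,
                "fraction": f,
                "se": math.sqrt(f * (1.0 - f) / total),
                "n": total,
                "sample_id": s.sample_id,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PredictionReport:
    max_abs_deviation: float
    agree: bool
    n_points: int
    tolerance_rule: str = "3*binomial SE + 0.02"


def compare_prediction(
    pred: CompetitionPrediction, observed: pd.DataFrame
) -> PredictionReport:
    """Maximum |predicted - observed| fraction and a per-point agreement flag.

    Each observed point must lie within 3 binomial standard errors plus an
    absolute 0.02 of the interpolated prediction.
    """
    obs = observed[
        (observed["t"] >= pred.t[0]) & (observed["t"] <= pred.t[-1])
    ]
    if obs.empty:
        raise ValueError("no overlapping time support between prediction and data")
    f_pred = np.interp(obs["t"].to_numpy(), pred.t, pred.f_t)
    dev = np.abs(f_pred - obs["fraction"].to_numpy())
    tol = 3.0 * obs["se"].to_numpy() + 0.02
    return PredictionReport(
        max_abs_deviation=float(dev.max()),
        agree=bool(np.all(dev <= tol)),
        n_points=len(obs),
    )


class CompetitionModel:
    """Two-label competition: prediction plus comparison to flow counts."""

    def __init__(
        self,
        comp_a: Competitor,
        comp_b: Competitor,
        inoculum_ratio: tuple[float, float] = (1.0, 1.0),
        *,
        horizon: float = 200.0,
        count_dead: bool = False,
    ) -> None:
        self.comp_a = comp_a
        self.comp_b = comp_b
        self.inoculum_ratio = inoculum_ratio
        self.horizon = horizon
        self.count_dead = count_dead

    def fit(self, samples: list[FlowSample] | None = None) -> "CompetitionResults":
        pred = predict_steady_state(
            self.comp_a,
            self.comp_b,
            self.inoculum_ratio,
            horizon=self.horizon,
            count_dead=self.count_dead,
        )
        observed = report = None
        if samples:
            observed = fraction_timecourse(
                samples, self.comp_a.label, include_dead=self.count_dead
            )
            report = compare_prediction(pred, observed)
        return CompetitionResults(self, pred, observed, report)


class CompetitionResults:
    def __init__(self, model, prediction, observed, report) -> None:
        self.model = model
        self.prediction = prediction
        self.observed = observed
        self.report = report

    f_inf = property(lambda self: self.prediction.f_inf)
    t_ss = property(lambda self: self.prediction.t_ss)

    def summary(self) -> str:
        p = self.prediction
        lines = [
            "Two-label competition analysis",
            "=" * 40,
            f"labels:                {self.model.comp_a.label} vs {self.model.comp_b.label}",
            f"predicted f_inf:       {p.f_inf:.4f}",
            f"time to steady state:  "
            + ("n/a" if math.isnan(p.t_ss) else f"{p.t_ss:.1f} h"),
            f"degenerate (r_A!=r_B): {p.degenerate}",
        ]
        if self.report is not None:
            lines.append(
                f"max |pred - obs|:      {self.report.max_abs_deviation:.4f} "
                f"(agree={self.report.agree}, n={self.report.n_points})"
            )
        return "\n".join(lines)


def plot_fractions(
    pred: CompetitionPrediction,
    observed: pd.DataFrame | None = None,
    labels: tuple[str, str] = ("A", "B"),
    ax=None,
):
    """Stacked-area plot of the predicted label fractions, with observations."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.fill_between(pred.t, 0, pred.f_t, color="#5cb85c", alpha=0.7, label=labels[0])
    ax.fill_between(pred.t, pred.f_t, 1, color="#d9534f", alpha=0.7, label=labels[1])
    if observed is not None:
        ax.errorbar(
            observed["t"], observed["fraction"], yerr=3 * observed["se"],
            fmt="ko", ms=4, label=f"{labels[0]} observed",
        )
    ax.axhline(pred.f_inf, ls="--", color="k", lw=1)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"fraction of {labels[0]}")
    ax.set_ylim(0, 1)
    ax.legend(loc="best", fontsize=8)
    return ax
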