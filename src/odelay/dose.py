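"""Dose-response analysis: tau vs dose, critical concentration, potency shift.

The critical concentration is operationalised as the smallest tested dose
whose recipient culture never doubles within the observation horizon
(censored tau); the potency shift of a background medium is the ratio of
the standalone to the on-background effect-threshold dose (smallest dose
inducing a delay phase).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .containers import ODTrace
from .curves import DEFAULT_MARGIN_H, DelayResult, classify_delay, measure_tau
from .params import DEFAULT_GROWTH, Condition, GrowthParams, ToxinResponse
from .synth import DEFAULT_HORIZON, DEFAULT_NOISE_SD, generate_od_trace

__all__ = [
    "DosePanelResult",
    "tau_dose_profile",
    "estimate_critical_concentration",
    "potency_shift",
    "analyze_dose_panel",
    "refine_critical_concentration",
    "DoseResponseModel",
]


@dataclass(frozen=True)
class DosePanelResult:
    """tau-vs-dose profile of one panel."""

    doses: tuple[float, ...]
    taus: tuple[float, ...]  # h; inf = censored
    delay_present: tuple[bool, ...]
    monotone_ok: bool
    c_crit_hat: float = math.nan  # mM; inf when no dose is censored
    censoring_consistent: bool = True

    @property
    def effect_threshold(self) -> float:
        """Smallest dose with a delay phase; inf if none."""
        for c, flag in zip(self.doses, self.delay_present):
            if flag:
                return c
        return math.inf


def tau_dose_profile(
    panel: Sequence[tuple[float, DelayResult]]
) -> DosePanelResult:
    """Order a (dose, DelayResult) panel and check tau monotonicity."""
    if len(panel) < 2:
        raise ValueError("panel needs at least two doses")
    doses = [c for c, _ in panel]
    if len(set(doses)) != len(doses):
        raise ValueError("duplicate doses in panel")
    if 0.0 not in doses:
        raise ValueError("panel must include the zero dose")
    panel = sorted(panel, key=lambda cr: cr[0])
    taus = [res.tau for _, res in panel]
    flags = [bool(res.delay_present) for _, res in panel]
    monotone = all(t2 >= t1 for t1, t2 in zip(taus, taus[1:]))
    return DosePanelResult(
        doses=tuple(c for c, _ in panel),
        taus=tuple(taus),
        delay_present=tuple(flags),
        monotone_ok=monotone,
    )


def estimate_critical_concentration(panel: DosePanelResult) -> DosePanelResult:
    """Smallest tested dose with censored tau (no doubling within horizon).

    Returns a copy of the panel with ``c_crit_hat`` filled in; ``inf`` when
    no dose is censored.  If a dose above the smallest censored one is
    uncensored, the censoring pattern is inconsistent: a warning is issued
    and the smallest censored dose still returned.
    """
    censored = [c for c, t in zip(panel.doses, panel.taus) if math.isinf(t)]
    if not censored:
        return replace(panel, c_crit_hat=math.inf)
    c_crit = min(censored)
    consistent = all(
        math.isinf(t) for c, t in zip(panel.doses, panel.taus) if c >= c_crit
    )
    if not consistent:
        warnings.warn(
            f"non-monotone censoring above {c_crit:g} mM; returning the "
            "smallest censored dose",
            stacklevel=2,
        )
    return replace(panel, c_crit_hat=c_crit, censoring_consistent=consistent)


def potency_shift(
    standalone_panel: DosePanelResult, background_panel: DosePanelResult
) -> float:
    """Standalone / on-background effect-threshold dose ratio (>=1: potentiation)."""
    c_alone = standalone_panel.effect_threshold
    c_bg = background_panel.effect_threshold
    if math.isinf(c_alone) or math.isinf(c_bg) or c_bg == 0:
        raise ValueError("effect threshold undefined in at least one panel")
    return c_alone / c_bg


def analyze_dose_panel(
    traces_by_dose: Sequence[tuple[float, ODTrace]],
    *,
    margin: float = DEFAULT_MARGIN_H,
) -> DosePanelResult:
    """Measure tau per dose, classify delays against the zero-dose baseline,
    and estimate the critical concentration."""
    results = []
    baseline: DelayResult | None = None
    for c, trace in sorted(traces_by_dose, key=lambda ct: ct[0]):
        res = measure_tau(trace, estimate_rate=False)
        results.append((c, res))
        if c == 0.0:
            baseline = res
    if baseline is None:
        raise ValueError("panel must include the zero dose")
    if baseline.censored:
        raise ValueError("zero-dose baseline never doubled; cannot classify delays")
    for _, res in results:
        classify_delay(res, baseline.tau, margin)
    return estimate_critical_concentration(tau_dose_profile(results))


def refine_critical_concentration(
    toxin: ToxinResponse,
    p: GrowthParams = DEFAULT_GROWTH,
    *,
    lo: float,
    hi: float,
    n_iter: int = 6,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
    noise_sd: float = DEFAULT_NOISE_SD,
    margin: float = DEFAULT_MARGIN_H,
) -> float:
    """Log-bisection refinement of the critical concentration.

    Generates fresh traces at each probe dose; ``lo`` must double within the
    horizon and ``hi`` must not.  Returns the midpoint of the final bracket.
    """
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    rng = np.random.default_rng(seed)
    baseline = measure_tau(
        generate_od_trace(p, Condition(), toxin, horizon, noise_sd, rng,
                          sample_id="refine_baseline"),
        estimate_rate=False,
    )
    for _ in range(n_iter):
        mid = math.sqrt(lo * hi)
        trace = generate_od_trace(
            p, Condition(effective_dose=mid), toxin, horizon, noise_sd, rng,
            sample_id=f"refine_{mid:g}mM",
        )
        res = measure_tau(trace, estimate_rate=False)
        classify_delay(res, baseline.tau, margin)
        if res.censored:
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)


class DoseResponseModel:
    """Model of a tau-vs-dose panel of OD traces.

    ``fit()`` measures tau at every dose, classifies delay phases against
    the zero-dose baseline and estimates the critical concentration; the
    result is a :class:`DosePanelResult` with a ``summary()`` wrapper.
    """

    def __init__(
        self,
        traces_by_dose: Sequence[tuple[float, ODTrace]],
        *,
        margin: float = DEFAULT_MARGIN_H,
    ) -> None:
        self.traces_by_dose = list(traces_by_dose)
        self.margin = margin

    @classmethod
    def from_traces(cls, traces: Sequence[ODTrace], **kw) -> "DoseResponseModel":
        pairs = [(float(tr.metadata.get("dose_mM", 0.0)), tr) for tr in traces]
        return cls(pairs, **kw)

    def fit(self) -> "DoseResponseResults":
        return DoseResponseResults(self, analyze_dose_panel(
            self.traces_by_dose, margin=self.margin
        ))


class DoseResponseResults:
    def __init__(self, model: DoseResponseModel, panel: DosePanelResult) -> None:
        self.model = model
        self.panel = panel

    c_crit_hat = property(lambda self: self.panel.c_crit_hat)
    monotone_ok = property(lambda self: self.panel.monotone_ok)
    effect_threshold = property(lambda self: self.panel.effect_threshold)

    def summary(self) -> str:
        lines = [
            "Dose-response delay analysis",
            "=" * 40,
            f"{'dose (mM)':>10}  {'tau (h)':>10}  delay",
        ]
        for c, t, f in zip(
            self.panel.doses, self.panel.taus, self.panel.delay_present
        ):
            tau = "censored" if math.isinf(t) else f"{t:10.2f}"
            lines.append(f"{c:10.2f}  {tau:>10}  {f}")
        cc = self.panel.c_crit_hat
        lines.append("-" * 40)
        lines.append(
            "critical concentration: "
            + ("not reached" if math.isinf(cc) else f"{cc:g} mM")
        )
        lines.append(f"tau monotone in dose:   {self.panel.monotone_ok}")
        return "\n".join(lines)
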