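"""Synthetic-data generators: the measurement layer over the forward model.

Turns deterministic trajectories into noisy 1-minute turbidimeter traces,
multinomial flow-cytometry count tables, conditioned-medium panels and
Venn-structured compound tables.  Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .containers import CompoundRecord, FlowSample, ODTrace
from .params import (
    DEFAULT_GROWTH,
    HICA,
    Condition,
    CultureState,
    GrowthParams,
    SecretionParams,
    ToxinResponse,
)
from .popdyn import cm_condition, kill_fraction, secrete_toxin, simulate_culture

__all__ = [
    "generate_od_trace",
    "generate_dose_panel",
    "generate_cm_series",
    "generate_flow_counts",
    "generate_compound_table",
    "DEFAULT_NOISE_SD",
    "DEFAULT_HORIZON",
]

DEFAULT_NOISE_SD = 0.02  # sd of multiplicative log-normal turbidimeter noise
DEFAULT_HORIZON = 75.0  # h, span of a typical multi-day growth assay
_FLOOR_RATIO = 0.1  # additive floor sd = noise_sd * _FLOOR_RATIO (OD units)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_od_trace(
    p: GrowthParams,
    cond: Condition,
    resp: ToxinResponse,
    horizon: float = DEFAULT_HORIZON,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator = 0,
    *,
    sample_id: str = "trace",
    floor_sd: float | None = None,
    metadata: dict | None = None,
) -> ODTrace:
    """Generate one noisy 1-minute OD trace for a condition.

    The deterministic trajectory from :func:`simulate_culture` receives
    multiplicative log-normal noise (sd ``noise_sd`` in log units) plus an
    additive Gaussian floor (default sd ``noise_sd/10`` OD, i.e. 0.002 OD at
    default noise), then clipping at zero.  ``noise_sd=0`` reproduces the
    deterministic trajectory exactly.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if floor_sd is None:
        floor_sd = noise_sd * _FLOOR_RATIO
    d = kill_fraction(cond.effective_dose, resp, cond)
    traj = simulate_culture(p, d, horizon, step=1.0 / 60.0)
    od = traj.od
    if noise_sd > 0 or floor_sd > 0:
        rng = _rng(seed)
        od = od * np.exp(rng.normal(0.0, noise_sd, size=od.shape))
        od = od + rng.normal(0.0, floor_sd, size=od.shape)
        od = np.clip(od, 0.0, None)
    meta = {
        "medium": cond.medium_label or ("MM+glc" if cond.glucose_present else "0% MM"),
        "dose_mM": cond.effective_dose,
        "preculture": "adapted" if cond.adapted else "unadapted",
    }
    if metadata:
        meta.update(metadata)
    # 1-min sampling: integer minute stamps avoid float drift from t*60
    return ODTrace(
        sample_id=sample_id,
        times_min=np.arange(od.size, dtype=float),
        od=od,
        metadata=meta,
    )


def generate_dose_panel(
    doses: Sequence[float],
    toxin: ToxinResponse,
    p: GrowthParams = DEFAULT_GROWTH,
    seed: int | np.random.Generator = 0,
    *,
    cond_base: Condition | None = None,
    horizon: float = DEFAULT_HORIZON,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[ODTrace]:
    """One trace per dose, drawn from a shared seeded noise stream."""
    if any(c < 0 for c in doses):
        raise ValueError("doses must be non-negative")
    if cond_base is None:
        cond_base = Condition()
    rng = _rng(seed)
    traces = []
    for c in doses:
        cond = Condition(
            glucose_present=cond_base.glucose_present,
            adapted=cond_base.adapted,
            effective_dose=float(c),
            cm_background=cond_base.cm_background,
            medium_label=f"0% MM + {c:g} mM",
        )
        traces.append(
            generate_od_trace(
                p, cond, toxin, horizon, noise_sd, rng,
                sample_id=f"dose_{c:g}mM",
                metadata={"dose_mM": float(c)},
            )
        )
    return traces


def generate_cm_series(
    incubation_times: Sequence[float],
    sp: SecretionParams,
    p: GrowthParams = DEFAULT_GROWTH,
    seed: int | np.random.Generator = 0,
    *,
    resp: ToxinResponse = HICA,
    horizon: float = DEFAULT_HORIZON,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[ODTrace]:
    """Recipient-culture traces for CM prepared with several incubation times.

    For each incubation time the producer's accumulated toxin signal is
    computed with :func:`secrete_toxin`, calibrated to an effective dose via
    :func:`cm_condition`, and the recipient trace generated from it.
    """
    if any(t < 0 for t in incubation_times):
        raise ValueError("incubation times must be non-negative")
    rng = _rng(seed)
    traces = []
    for t_inc in incubation_times:
        signal = secrete_toxin(p, sp, t_inc)
        cond = cm_condition(
            signal, sp, resp, p, medium_label=f"CM-{t_inc:g}h"
        )
        traces.append(
            generate_od_trace(
                p, cond, resp, horizon, noise_sd, rng,
                sample_id=f"cm_{t_inc:g}h",
                metadata={"incubation_h": float(t_inc)},
            )
        )
    return traces


def generate_flow_counts(
    states: dict[str, CultureState],
    total_events: int,
    count_dead: bool = True,
    seed: int | np.random.Generator = 0,
    *,
    sample_id: str = "flow",
) -> FlowSample:
    """Multinomial flow-cytometry draw over (label x viability) gates.

    Gate probabilities are proportional to the subpopulation masses; the
    dead compartments participate only when ``count_dead`` is true (dead
    cells then score in the ``<label>_dead`` gate, e.g. as dye-positive).
    """
    if total_events <= 0:
        raise ValueError("total_events must be positive")
    gates: list[str] = []
    masses: list[float] = []
    t = 0.0
    for label, st in states.items():
        t = st.t
        gates.append(f"{label}_live")
        masses.append(st.living)
        if count_dead:
            gates.append(f"{label}_dead")
            masses.append(st.dead)
    m = np.asarray(masses, dtype=float)
    if not np.any(m > 0):
        raise ValueError("all subpopulation masses are zero; gate probabilities undefined")
    probs = m / m.sum()
    rng = _rng(seed)
    counts = rng.multinomial(total_events, probs)
    return FlowSample(
        sample_id=sample_id, t=t, counts=dict(zip(gates, counts.tolist()))
    )


def generate_compound_table(
    n_shared: int,
    n_also_in_mm: int,
    n_noncm: int,
    seed: int | np.random.Generator = 0,
    *,
    n_pass: int = 2,
) -> list[CompoundRecord]:
    """Venn-structured compound table emulating a CM metabolite screen.

    ``n_shared`` compounds are detected in both wild-type and fbp1-deletion
    CM; ``n_also_in_mm`` of those are also in fresh medium, so the
    candidate region (both CMs, not fresh medium) has ``n_shared -
    n_also_in_mm`` members.  ``n_noncm`` extra compounds are scattered over
    the non-candidate regions.  Exactly ``min(n_pass, region size)``
    candidate-region compounds carry criterion flags that survive the
    candidate filter; the rest fail at least one criterion.
    """
    if n_also_in_mm > n_shared:
        raise ValueError(
            f"n_also_in_mm ({n_also_in_mm}) cannot exceed n_shared ({n_shared})"
        )
    if min(n_shared, n_also_in_mm, n_noncm) < 0:
        raise ValueError("counts must be non-negative")
    rng = _rng(seed)
    records: list[CompoundRecord] = []
    idx = 0

    def flags(passing: bool) -> dict:
        if passing:
            return dict(
                changes_postdelay_growth=False,
                affects_growth_with_glucose=False,
                delays_adapted_cells=False,
            )
        # fail at least one criterion, chosen at random
        f = [bool(rng.integers(0, 2)) for _ in range(3)]
        if not any(f):
            f[int(rng.integers(0, 3))] = True
        return dict(
            changes_postdelay_growth=f[0],
            affects_growth_with_glucose=f[1],
            delays_adapted_cells=f[2],
        )

    n_candidate = n_shared - n_also_in_mm
    n_passing = min(n_pass, n_candidate)
    pass_slots = set(rng.choice(n_candidate, size=n_passing, replace=False).tolist()) if n_candidate else set()
    slot = 0
    for i in range(n_shared):
        in_mm = i < n_also_in_mm
        if in_mm:
            fl = flags(False)
        else:
            fl = flags(slot in pass_slots)
            slot += 1
        records.append(
            CompoundRecord(
                compound=f"C{idx:03d}", in_mm=in_mm, in_wt_cm=True,
                in_fbp1_cm=True, **fl,
            )
        )
        idx += 1
    # non-candidate extras: memberships outside (WT ∩ fbp1) \ MM
    noncm_patterns = [
        dict(in_mm=True, in_wt_cm=False, in_fbp1_cm=False),
        dict(in_mm=False, in_wt_cm=True, in_fbp1_cm=False),
        dict(in_mm=False, in_wt_cm=False, in_fbp1_cm=True),
        dict(in_mm=True, in_wt_cm=True, in_fbp1_cm=False),
        dict(in_mm=True, in_wt_cm=False, in_fbp1_cm=True),
    ]
    for _ in range(n_noncm):
        pat = noncm_patterns[int(rng.integers(0, len(noncm_patterns)))]
        records.append(
            CompoundRecord(compound=f"C{idx:03d}", **pat, **flags(False))
        )
        idx += 1
    return records
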