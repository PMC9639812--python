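"""Parameter containers for the two-compartment culture model.

The model describes a fission-yeast-style batch culture in glucose-free
minimal medium in which secreted autotoxins (HICA, 2K3MVA) kill a fraction
of an unadapted inoculum on exposure.  Dead cells keep scattering light, so
the observed optical density is the sum of a constant dead compartment and
a growing living compartment — the apparent "delay phase" of the OD trace
is an optical artifact of this masking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "LN2",
    "GrowthParams",
    "ToxinResponse",
    "Condition",
    "CultureState",
    "SecretionParams",
    "DEFAULT_GROWTH",
    "HICA",
    "MVA_2K3",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthParams:
    """Per-strain, per-condition kinetic parameters.

    Parameters
    ----------
    r : float
        Exponential growth rate at the steady growth phase, 1/h.
    lag : float
        Survivor lag before regrowth starts, h.
    K : float
        Carrying capacity of the culture in OD units.
    a0 : float
        Inoculum optical density at t = 0 (living + soon-to-die cells).
    """

    r: float
    lag: float = 0.0
    K: float = 1.0
    a0: float = 0.005

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"growth rate r must be positive, got {self.r}")
        if self.lag < 0:
            raise ValueError(f"lag must be non-negative, got {self.lag}")
        if not (0 < self.a0 < self.K):
            raise ValueError(
                f"inoculum a0 must satisfy 0 < a0 < K, got a0={self.a0}, K={self.K}"
            )

    @property
    def doubling_time(self) -> float:
        """Doubling time ln(2)/r of the steady growth phase, h."""
        return LN2 / self.r

    def replace(self, **kwargs) -> "GrowthParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ToxinResponse:
    """Dose -> kill-fraction response of unadapted cells to one autotoxin.

    Below the critical concentration ``c_crit`` the kill fraction follows a
    Hill curve saturating at ``d_max``; at or above ``c_crit`` killing is
    complete and growth is fully suppressed.  ``s`` is the potency
    multiplier applied when the toxin is administered on a conditioned-medium
    background (the medium sensitises cells, lowering the effective dose
    needed by orders of magnitude).
    """

    c_crit: float  # mM; at/above this dose the kill fraction is 1
    h: float  # mM; half-effect concentration of the sub-critical Hill curve
    n: float = 4.0  # Hill steepness
    d_max: float = 0.97  # maximal sub-critical kill fraction
    s: float = 1000.0  # conditioned-medium potency multiplier

    def __post_init__(self) -> None:
        if not (0 < self.h < self.c_crit):
            raise ValueError(
                f"require 0 < h < c_crit, got h={self.h}, c_crit={self.c_crit}"
            )
        if self.n < 1:
            raise ValueError(f"Hill steepness n must be >= 1, got {self.n}")
        if not (0 <= self.d_max < 1):
            raise ValueError(f"d_max must lie in [0, 1), got {self.d_max}")
        if self.s < 1:
            raise ValueError(f"potency multiplier s must be >= 1, got {self.s}")


@dataclass(frozen=True)
class Condition:
    """Environmental context of one culture."""

    glucose_present: bool = False
    adapted: bool = False
    effective_dose: float = 0.0  # mM toxin-equivalent after calibration
    cm_background: bool = False  # toxin administered on conditioned medium
    medium_label: str = ""

    def __post_init__(self) -> None:
        if self.effective_dose < 0:
            raise ValueError(
                f"effective_dose must be non-negative, got {self.effective_dose}"
            )


@dataclass(frozen=True)
class CultureState:
    """Instantaneous state of a culture; observed OD is living + dead."""

    living: float
    dead: float
    t: float  # h

    def __post_init__(self) -> None:
        if self.living < 0 or self.dead < 0:
            raise ValueError("living and dead OD must be non-negative")

    @property
    def od(self) -> float:
        return self.living + self.dead


@dataclass(frozen=True)
class SecretionParams:
    """Toxin secretion during conditioned-medium preparation.

    Secretion per culture scales with the square of cell density (per-cell
    rate proportional to density), starting after an induction delay
    ``t_ind``.  ``E_thresh`` is the accumulated-signal threshold above which
    the resulting conditioned medium induces a delay phase in recipients.
    """

    t_ind: float  # h, induction delay before secretion starts
    k: float  # concentration * OD^-2 * h^-1
    E_thresh: float  # delay-inducing accumulated-signal threshold

    def __post_init__(self) -> None:
        if self.t_ind < 0:
            raise ValueError(f"t_ind must be non-negative, got {self.t_ind}")
        if not self.k > 0:
            raise ValueError(f"secretion coefficient k must be positive, got {self.k}")
        if not self.E_thresh > 0:
            raise ValueError(f"E_thresh must be positive, got {self.E_thresh}")


# Default calibration: 10-h doubling in glucose-free minimal medium,
# carrying cap 1.0 OD, inoculum 0.005 OD.
DEFAULT_GROWTH = GrowthParams(r=LN2 / 10.0, lag=0.0, K=1.0, a0=0.005)

# Leucic acid (2-hydroxyisocaproic acid): growth fully suppressed at 30 mM.
HICA = ToxinResponse(c_crit=30.0, h=20.0, n=4.0, d_max=0.97, s=1000.0)

# L-2-keto-3-methylvalerate: growth fully suppressed at 25 mM.
MVA_2K3 = ToxinResponse(c_crit=25.0, h=16.0, n=4.0, d_max=0.97, s=1000.0)
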