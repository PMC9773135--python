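"""Weibull survival curves and partitioned-survival state occupancy.

The cohort model has three states — progression-free (PFS), progressed
disease (PD) and death — whose per-cycle occupancy is derived from two
independently extrapolated Weibull curves per arm (PFS and OS) by the
partitioned-survival ("area under the curve") construction:

    dead(t) = 1 - S_OS(t)          (with a background-mortality hazard floor)
    pfs(t)  = min(S_PFS(t), 1 - dead(t))
    pd(t)   = alive(t) - pfs(t)

Subgroup treatment-arm curves are obtained from the comparator baseline by
Weibull proportional hazards: multiplying the scale by the subgroup hazard
ratio leaves the shape unchanged and equals raising S(t) to the power HR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import ModelSettings, ParameterSet, WeibullParams

__all__ = [
    "SurvivalCurve",
    "SubgroupSpec",
    "Occupancy",
    "weibull_S",
    "weibull_median",
    "per_cycle_event_prob",
    "occupancy",
    "find_horizon",
    "subgroup_curves",
]


def weibull_S(p: WeibullParams, t) -> float | np.ndarray:
    """Survival probability S(t) = exp(-scale * t**shape) at cycle time t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be nonnegative")
    out = np.exp(-p.scale * np.power(t, p.shape))
    return float(out) if out.ndim == 0 else out


def weibull_median(p: WeibullParams) -> float:
    """Cycle time at which S(t) = 1/2 (closed form)."""
    return (math.log(2.0) / p.scale) ** (1.0 / p.shape)


def per_cycle_event_prob(p: WeibullParams, t: int) -> float:
    """Conditional probability q(t) = 1 - S(t)/S(t-1) of the event in cycle t.

    By convention returns 1 when S(t-1) has underflowed to zero.
    """
    if t < 1:
        raise ValueError("cycle index must be >= 1")
    s_prev = weibull_S(p, t - 1)
    if s_prev == 0.0:
        return 1.0
    return 1.0 - weibull_S(p, t) / s_prev


@dataclass(frozen=True)
class SurvivalCurve:
    """A labelled Weibull curve for one endpoint of one arm."""

    params: WeibullParams
    endpoint: str  # "pfs" | "os"
    arm: str       # "sidchm" | "plchm"

    def __call__(self, t):
        return weibull_S(self.params, t)

    def median(self) -> float:
        return weibull_median(self.params)


@dataclass(frozen=True)
class SubgroupSpec:
    """A patient subgroup defined by its OS and PFS hazard ratios.

    Optional 95 % confidence intervals feed the log-normal hazard-ratio
    sampling of the subgroup probabilistic analysis.
    """

    name: str
    hr_os: float
    hr_pfs: float
    hr_os_ci: tuple[float, float] | None = None
    hr_pfs_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.hr_os <= 0 or self.hr_pfs <= 0:
            raise ValueError("hazard ratios must be positive")
        for ci in (self.hr_os_ci, self.hr_pfs_ci):
            if ci is not None and not (0 < ci[0] <= ci[1]):
                raise ValueError(f"invalid hazard-ratio confidence interval {ci}")


@dataclass(frozen=True)
class Occupancy:
    """Per-cycle state fractions for one arm, cycles 0..T inclusive."""

    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    reconciled_cycles: int  # cycles where extrapolated PFS exceeded OS

    def __len__(self) -> int:
        return len(self.pfs)


def _background_cycle_hazard(settings: ModelSettings) -> float:
    """Constant all-cause mortality converted to a per-cycle hazard."""
    annual_p = settings.background_mortality_annual
    return -math.log(1.0 - annual_p) * settings.cycle_years


def death_curve(os_params: WeibullParams, settings: ModelSettings, n_cycles: int) -> np.ndarray:
    """Cumulative death fraction over cycles 0..n, OS hazard floored by
    background mortality."""
    t = np.arange(n_cycles + 1, dtype=float)
    s_os = weibull_S(os_params, t)
    with np.errstate(divide="ignore"):
        # per-cycle hazards implied by the OS curve; inf when S underflows
        haz = -np.diff(np.log(np.maximum(s_os, 1e-300)))
    haz = np.maximum(haz, _background_cycle_hazard(settings))
    alive = np.concatenate([[1.0], np.exp(-np.cumsum(haz))])
    return 1.0 - alive


def occupancy(pfs_params: WeibullParams, os_params: WeibullParams,
              settings: ModelSettings, n_cycles: int) -> Occupancy:
    """Partitioned-survival state occupancy for one arm over cycles 0..n.

    Curve crossing (extrapolated PFS above OS) is reconciled by capping the
    PFS occupancy at the alive fraction; the number of affected cycles is
    reported on the result.
    """
    t = np.arange(n_cycles + 1, dtype=float)
    dead = death_curve(os_params, settings, n_cycles)
    alive = 1.0 - dead
    s_pfs = weibull_S(pfs_params, t)
    reconciled = int(np.sum(s_pfs > alive + 1e-15))
    pfs = np.minimum(s_pfs, alive)
    pd = alive - pfs
    return Occupancy(pfs=pfs, pd=pd, dead=dead, reconciled_cycles=reconciled)


def find_horizon(ps: ParameterSet) -> tuple[int, bool]:
    """First cycle at which the cumulative death fraction reaches the horizon
    threshold in *both* arms; capped at ``settings.max_cycles``.

    Returns ``(horizon, capped)`` where ``capped`` flags that the threshold
    was not reached before the cap.
    """
    st = ps.settings
    cap = st.max_cycles
    thresh = st.death_horizon_threshold
    deads = [death_curve(ps.weibull[f"{arm}_os"], st, cap) for arm in ("sidchm", "plchm")]
    both = np.minimum(*deads)
    hit = np.nonzero(both >= thresh)[0]
    if hit.size:
        return int(hit[0]), False
    return cap, True


def subgroup_curves(ps: ParameterSet, sg: SubgroupSpec) -> dict[str, WeibullParams]:
    """Treatment-arm subgroup curves from the comparator baseline.

    Under Weibull proportional hazards the subgroup SIDCHM curve is the
    overall PLCHM curve with its scale multiplied by the subgroup hazard
    ratio (shape unchanged), separately for OS and PFS; the comparator
    subgroup curves equal the overall comparator curves.
    """
    base_os = ps.weibull["plchm_os"]
    base_pfs = ps.weibull["plchm_pfs"]
    return {
        "sidchm_os": WeibullParams(scale=base_os.scale * sg.hr_os, shape=base_os.shape),
        "sidchm_pfs": WeibullParams(scale=base_pfs.scale * sg.hr_pfs, shape=base_pfs.shape),
        "plchm_os": base_os,
        "plchm_pfs": base_pfs,
    }
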