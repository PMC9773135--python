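"""Per-cycle costs and utilities for each arm.

Drug acquisition is costed from per-100 mg tender prices: chemotherapy
doses scale with body surface area (cisplatin 75 mg/m², paclitaxel
175 mg/m², fluorouracil 800 mg/m² per 21-day cycle, for at most six
cycles) weighted by the regimen mix, and sintilimab is a flat 200 mg per
cycle in the treatment arm for at most the configured number of cycles
(24-month cap). Pricing is linear per mg by default; a vial-rounding mode
(ceil to whole 100 mg vials) is available via settings.

Beyond drugs, patients in the progression-free state accrue follow-up and
laboratory/radiology test costs each cycle; progressed patients accrue
best supportive care plus (configurably) follow-up and tests. Grade >=3
adverse-event management is an incidence-weighted lump sum at model entry,
and end-of-life care is a one-time cost attached to the cycle of death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import AE_NAMES, ParameterSet

__all__ = [
    "CyclePayoffs",
    "CHEMO_DOSES_MG_PER_M2",
    "SINTILIMAB_DOSE_MG",
    "drug_price",
    "drug_cost_per_cycle",
    "ae_onetime_cost",
    "build_payoffs",
]

#: per-cycle chemotherapy doses, mg per m² of body surface area
CHEMO_DOSES_MG_PER_M2 = {"cisplatin": 75.0, "paclitaxel": 175.0, "fluorouracil": 800.0}
#: flat sintilimab dose per cycle, mg
SINTILIMAB_DOSE_MG = 200.0


@dataclass(frozen=True)
class CyclePayoffs:
    """Cost and QALY accrual rules for one arm, cycles 1..T.

    ``cost_pfs``/``cost_pd`` are USD per full cycle spent in the state
    (index 0 corresponds to cycle 1); the one-time entries are incurred at
    model entry (AE management) and at death (end-of-life care).
    """

    cost_pfs: np.ndarray
    cost_pd: np.ndarray
    cost_onetime_start: float
    cost_onetime_death: float
    qaly_pfs_per_cycle: float
    qaly_pd_per_cycle: float


def drug_price(ps: ParameterSet, drug: str, mg: float) -> float:
    """Acquisition cost of ``mg`` milligrams of a drug.

    Linear per-mg pricing by default; with ``settings.vial_rounding`` the
    quantity is rounded up to whole 100 mg vials (no vial sharing).
    """
    if mg < 0:
        raise ValueError("drug quantity must be nonnegative")
    per_100mg = ps.value(f"price_{drug}")
    if ps.settings.vial_rounding:
        return math.ceil(mg / 100.0) * per_100mg
    return mg / 100.0 * per_100mg


def drug_cost_per_cycle(arm: str, t: int, ps: ParameterSet) -> float:
    """Expected drug acquisition cost for cycle ``t`` (t >= 1) in one arm.

    The chemotherapy backbone (shared by both arms; placebo itself is
    costless) applies while t <= chemo_max_cycles, as the regimen-mix
    weighted sum of the two doublets. Sintilimab applies in the treatment
    arm while t <= sintilimab_max_cycles.
    """
    if t < 1:
        raise ValueError("cycle index must be >= 1")
    bsa = ps.value("bsa")
    if bsa <= 0:
        raise ValueError("body surface area must be positive")
    cost = 0.0
    if t <= ps.settings.chemo_max_cycles:
        cis = drug_price(ps, "cisplatin", CHEMO_DOSES_MG_PER_M2["cisplatin"] * bsa)
        pac = drug_price(ps, "paclitaxel", CHEMO_DOSES_MG_PER_M2["paclitaxel"] * bsa)
        fu5 = drug_price(ps, "fluorouracil", CHEMO_DOSES_MG_PER_M2["fluorouracil"] * bsa)
        cost += ps.value("prop_paclitaxel") * (cis + pac)
        cost += ps.value("prop_fluorouracil") * (cis + fu5)
    if arm == "sidchm" and t <= ps.settings.sintilimab_max_cycles:
        cost += drug_price(ps, "sintilimab", SINTILIMAB_DOSE_MG)
    return cost


def ae_onetime_cost(arm: str, ps: ParameterSet) -> float:
    """Incidence-weighted grade >=3 adverse-event management cost, applied
    once at model entry."""
    inc = ps.ae_incidences(arm)
    cost = ps.ae_costs()
    if set(inc) != set(cost) or set(inc) != set(AE_NAMES):
        raise ValueError("adverse-event incidence and cost inventories do not match")
    return sum(inc[ae] * cost[ae] for ae in AE_NAMES)


def build_payoffs(arm: str, ps: ParameterSet, n_cycles: int) -> CyclePayoffs:
    """Assemble the full per-cycle cost/QALY schedule for one arm."""
    st = ps.settings
    followup = ps.value("cost_followup_per_cycle")
    tests = ps.value("cost_tests")
    bsc = ps.value("cost_bsc")

    t = np.arange(1, n_cycles + 1)
    drug = np.array([drug_cost_per_cycle(arm, int(k), ps) for k in t])
    cost_pfs = drug + followup + tests
    cost_pd = np.full(n_cycles, bsc, dtype=float)
    if st.followup_in_pd:
        cost_pd += followup
    if st.tests_in_pd:
        cost_pd += tests

    cyc_years = st.cycle_years
    return CyclePayoffs(
        cost_pfs=cost_pfs,
        cost_pd=cost_pd,
        cost_onetime_start=ae_onetime_cost(arm, ps),
        cost_onetime_death=ps.value("cost_end_of_life"),
        qaly_pfs_per_cycle=ps.value("utility_pfs") * cyc_years,
        qaly_pd_per_cycle=ps.value("utility_pd") * cyc_years,
    )
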