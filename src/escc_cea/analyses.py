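"""Sensitivity and subgroup analyses around the base-case comparison.

* One-way (deterministic) sensitivity analysis: each parameter is pushed to
  its range limits with everything else at base, producing the tornado
  ordering of ICER swings.
* Probabilistic sensitivity analysis (PSA): Monte-Carlo resampling of all
  non-fixed parameters from Beta/Gamma/Normal families with moments matched
  to the tabulated base value and range, yielding the incremental
  cost/effect cloud and the cost-effectiveness acceptability curve (CEAC).
* Subgroup analysis: treatment-arm survival rebuilt from subgroup hazard
  ratios under Weibull proportional hazards, with optional log-normal
  hazard-ratio sampling for subgroup-level acceptability.

Moment matching: the tabulated min-max ranges are uniform plausibility
bands of base +/- 20 %, so the default dispersion rule reads them as mean
+/- one standard deviation (SE = (high - low)/2). The alternative reading
of the range as a 95 % confidence interval (SE = (high - low)/3.92) is
available via ``se_rule="ci95"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import CEResult, compare, run_arm, run_model
from .parameters import ModelParameter, ParameterSet
from .survival import SubgroupSpec, find_horizon, subgroup_curves

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACPoint",
    "SubgroupResult",
    "one_way_sa",
    "sample_psa",
    "ceac",
    "subgroup_analysis",
    "builtin_subgroups",
]


# ---------------------------------------------------------------------------
# one-way sensitivity analysis

@dataclass(frozen=True)
class TornadoEntry:
    """ICER excursion of one parameter swept across its range."""

    parameter: str
    base_value: float
    icer_at_low: float | None
    icer_at_high: float | None
    swing: float
    undefined_ends: int = 0  # ends where dominance left the ICER undefined

    def as_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "base": self.base_value,
            "icer_low": self.icer_at_low,
            "icer_high": self.icer_at_high,
            "swing": self.swing,
        }


def one_way_sa(ps: ParameterSet, parameters: list[str] | None = None) -> list[TornadoEntry]:
    """Sweep each parameter to its low and high bound and record the ICER.

    Weibull curve parameters are excluded (no published ranges). Entries are
    sorted by descending swing, ties broken alphabetically. An end at which
    dominance makes the ICER undefined is flagged and the swing computed
    from the defined ends only.
    """
    names = parameters if parameters is not None else list(ps.params)
    base_ce = run_model(ps)
    base_icer = base_ce.icer
    entries = []
    for name in names:
        p = ps[name]
        icers = {}
        for bound in ("low", "high"):
            v = getattr(p, bound)
            ce = run_model(ps.with_values({name: v}))
            icers[bound] = ce.icer
        defined = [v for v in icers.values() if v is not None]
        if len(defined) == 2:
            swing = abs(icers["high"] - icers["low"])
        elif len(defined) == 1 and base_icer is not None:
            swing = abs(defined[0] - base_icer)
        else:
            swing = 0.0
        entries.append(TornadoEntry(
            parameter=name, base_value=p.base,
            icer_at_low=icers["low"], icer_at_high=icers["high"],
            swing=swing, undefined_ends=2 - len(defined),
        ))
    entries.sort(key=lambda e: (-e.swing, e.parameter))
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def _moment_matched_sampler(p: ModelParameter, se_rule: str):
    """Return ``draw(rng) -> float`` for one parameter, or None if fixed.

    Mean equals the base value; the standard error derives from the range
    per ``se_rule``. Infeasible Beta moment matches (SE too large) fall
    back to the tighter ci95 rule, then to the base value.
    """
    if p.dist == "fixed" or p.high == p.low:
        return None
    mu = p.base
    divisor = {"range": 2.0, "ci95": 2.0 * 1.959963984540054}[se_rule]
    se = (p.high - p.low) / divisor

    if p.dist == "beta":
        if se * se >= mu * (1.0 - mu):
            se = (p.high - p.low) / (2.0 * 1.959963984540054)
        if se * se >= mu * (1.0 - mu) or mu <= 0 or mu >= 1:
            return None
        nu = mu * (1.0 - mu) / (se * se) - 1.0
        a, b = mu * nu, (1.0 - mu) * nu
        return lambda rng: float(rng.beta(a, b))
    if p.dist == "gamma":
        if mu <= 0:
            return None
        shape = (mu / se) ** 2
        scale = se * se / mu
        return lambda rng: float(rng.gamma(shape, scale))
    if p.dist == "normal":
        # truncated at zero (body surface area cannot be negative)
        a = (0.0 - mu) / se
        return lambda rng: float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=se,
                                                     random_state=rng))
    raise ValueError(f"unknown distribution {p.dist!r} for parameter {p.name!r}")


@dataclass(frozen=True)
class PSASample:
    """One Monte-Carlo realization: sampled values and per-arm outcomes."""

    values: dict[str, float]
    cost_sidchm: float
    qaly_sidchm: float
    cost_plchm: float
    qaly_plchm: float

    @property
    def delta_cost(self) -> float:
        return self.cost_sidchm - self.cost_plchm

    @property
    def delta_qaly(self) -> float:
        return self.qaly_sidchm - self.qaly_plchm


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float


@dataclass
class PSAResult:
    """Collected PSA draws with derived incremental quantities."""

    samples: list[PSASample]
    seed: int

    @property
    def delta_cost(self) -> np.ndarray:
        return np.array([s.delta_cost for s in self.samples])

    @property
    def delta_qaly(self) -> np.ndarray:
        return np.array([s.delta_qaly for s in self.samples])

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of draws in which treatment has the higher net monetary
        benefit at the given willingness-to-pay."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
        })


def sample_psa(ps: ParameterSet, n: int, seed: int,
               se_rule: str = "range") -> PSAResult:
    """Run ``n`` Monte-Carlo replications of the full model.

    Every non-fixed parameter is redrawn each iteration from its
    moment-matched family (survival-curve parameters are not varied: no
    published ranges); the cohort model then runs both arms per draw.
    Reproducible per-iteration substreams derive from the single seed.
    """
    if n < 1:
        raise ValueError("need at least one PSA iteration")
    samplers = {name: _moment_matched_sampler(p, se_rule)
                for name, p in ps.params.items()}
    horizon, capped = find_horizon(ps)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
    samples = []
    for rng in streams:
        values = {name: draw(rng) for name, draw in samplers.items() if draw is not None}
        psi = ps.with_values(values)
        a = run_arm("sidchm", psi, horizon=horizon, horizon_capped=capped)
        b = run_arm("plchm", psi, horizon=horizon, horizon_capped=capped)
        samples.append(PSASample(
            values=values,
            cost_sidchm=a.total_cost, qaly_sidchm=a.total_qaly,
            cost_plchm=b.total_cost, qaly_plchm=b.total_qaly,
        ))
    return PSAResult(samples=samples, seed=seed)


def ceac(result: PSAResult, wtp_grid=None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid
    (default $0 to $80,000 in $1,000 steps)."""
    if not result.samples:
        raise ValueError("need at least one PSA sample")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 80001.0, 1000.0)
    dq, dc = result.delta_qaly, result.delta_cost
    return [CEACPoint(wtp=float(w), probability=float(np.mean(w * dq - dc > 0.0)))
            for w in np.asarray(wtp_grid, dtype=float)]


# ---------------------------------------------------------------------------
# subgroup analysis

@dataclass(frozen=True)
class SubgroupResult:
    spec: SubgroupSpec
    ce: CEResult
    prob_cost_effective: float | None = None

    def as_row(self) -> dict:
        ce = self.ce
        return {
            "subgroup": self.spec.name,
            "hr_os": self.spec.hr_os,
            "hr_pfs": self.spec.hr_pfs,
            "delta_cost": ce.delta_cost,
            "delta_qaly": ce.delta_qaly,
            "icer": ce.dominance or ce.icer,
            "cost_effective": ce.cost_effective,
            "prob_cost_effective": self.prob_cost_effective,
        }


def _lognormal_hr_sampler(hr: float, ci: tuple[float, float] | None):
    if ci is None:
        return None
    lo, hi = ci
    if not (0 < lo <= hi):
        raise ValueError(f"invalid hazard-ratio confidence interval ({lo}, {hi})")
    sigma = (math.log(hi) - math.log(lo)) / (2.0 * 1.959963984540054)
    mu = math.log(hr)
    return lambda rng: float(rng.lognormal(mu, sigma)) if sigma > 0 else hr


def subgroup_analysis(ps: ParameterSet, subgroups: list[SubgroupSpec],
                      psa_n: int = 0, seed: int = 0,
                      se_rule: str = "range") -> list[SubgroupResult]:
    """Cost-effectiveness per subgroup.

    The treatment arm's curves are rebuilt from the subgroup hazard ratios
    (comparator stays at the overall baseline) and both arms rerun. With
    ``psa_n`` > 0 a subgroup-level PSA additionally samples the hazard
    ratios log-normally from their 95 % CIs together with the usual
    parameter distributions, yielding the probability of cost-effectiveness
    at the configured willingness-to-pay.
    """
    out = []
    samplers = {name: _moment_matched_sampler(p, se_rule)
                for name, p in ps.params.items()}
    for k, sg in enumerate(subgroups):
        ce = run_model(ps, curves=subgroup_curves(ps, sg))
        prob = None
        if psa_n > 0:
            hr_os_draw = _lognormal_hr_sampler(sg.hr_os, sg.hr_os_ci)
            hr_pfs_draw = _lognormal_hr_sampler(sg.hr_pfs, sg.hr_pfs_ci)
            streams = np.random.SeedSequence((seed, k)).spawn(psa_n)
            wins = 0
            for s in streams:
                rng = np.random.default_rng(s)
                values = {name: draw(rng) for name, draw in samplers.items()
                          if draw is not None}
                sgi = SubgroupSpec(
                    name=sg.name,
                    hr_os=hr_os_draw(rng) if hr_os_draw else sg.hr_os,
                    hr_pfs=hr_pfs_draw(rng) if hr_pfs_draw else sg.hr_pfs,
                )
                psi = ps.with_values(values)
                cei = run_model(psi, curves=subgroup_curves(psi, sgi))
                wins += cei.cost_effective
            prob = wins / psa_n
        out.append(SubgroupResult(spec=sg, ce=ce, prob_cost_effective=prob))
    return out


def builtin_subgroups() -> list[SubgroupSpec]:
    """ORIENT-15 subgroup hazard ratios (OS and PFS, with 95 % CIs)."""
    rows = [
        ("men", 0.64, (0.51, 0.81), 0.56, (0.46, 0.69)),
        ("women", 0.57, (0.29, 1.12), 0.60, (0.34, 1.07)),
        ("age<65", 0.70, (0.54, 0.92), 0.66, (0.52, 0.84)),
        ("age>=65", 0.54, (0.38, 0.77), 0.45, (0.32, 0.62)),
        ("weight<60kg", 0.67, (0.51, 0.88), 0.59, (0.46, 0.76)),
        ("weight>=60kg", 0.59, (0.41, 0.83), 0.51, (0.38, 0.69)),
        ("china", 0.63, (0.51, 0.78), 0.56, (0.46, 0.68)),
        ("ecog_0", 0.59, (0.36, 0.96), 0.68, (0.46, 1.00)),
        ("ecog_1", 0.64, (0.50, 0.81), 0.52, (0.42, 0.65)),
        ("metastatic", 0.62, (0.49, 0.77), 0.57, (0.46, 0.69)),
        ("locally_advanced", 0.77, (0.41, 1.44), 0.54, (0.29, 1.00)),
        ("no_hepatic_metastasis", 0.64, (0.50, 0.82), 0.54, (0.43, 0.67)),
        ("hepatic_metastasis", 0.60, (0.40, 0.91), 0.63, (0.44, 0.91)),
        ("chemo_paclitaxel", 0.65, (0.52, 0.80), 0.55, (0.45, 0.67)),
        ("chemo_fluorouracil", 0.31, (0.08, 1.20), 0.55, (0.23, 1.32)),
        ("cps<10", 0.62, (0.45, 0.85), 0.53, (0.40, 0.71)),
        ("cps>=10", 0.64, (0.48, 0.85), 0.58, (0.45, 0.75)),
        ("cps<5", 0.56, (0.37, 0.86), 0.51, (0.35, 0.75)),
        ("cps>=5", 0.65, (0.51, 0.83), 0.58, (0.47, 0.73)),
        ("cps<1", 1.32, (0.63, 2.77), 0.76, (0.41, 1.38)),
        ("cps>=1", 0.59, (0.47, 0.74), 0.54, (0.44, 0.66)),
        ("tps<10", 0.67, (0.52, 0.88), 0.56, (0.44, 0.71)),
        ("tps>=10", 0.55, (0.38, 0.78), 0.54, (0.39, 0.74)),
        ("tps<5", 0.61, (0.46, 0.82), 0.57, (0.44, 0.73)),
        ("tps>=5", 0.67, (0.49, 0.92), 0.54, (0.40, 0.73)),
        ("tps<1", 0.71, (0.53, 0.95), 0.52, (0.39, 0.68)),
        ("tps>=1", 0.63, (0.51, 0.78), 0.59, (0.46, 0.77)),
    ]
    return [SubgroupSpec(name=n, hr_os=ho, hr_os_ci=cio, hr_pfs=hp, hr_pfs_ci=cip)
            for n, ho, cio, hp, cip in rows]
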