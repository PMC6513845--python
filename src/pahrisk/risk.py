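"""Monte-Carlo daily intake and incremental lifetime cancer risk.

Daily intake of BaP-equivalent PAHs by inhalation:

    DI = TEQ * IR * ET / 24            [ng/day, TEQ in ng/m^3]

Incremental lifetime cancer risk:

    ILCR = TEQ_pg * IR * CF * ED * ET * EF * CSF / (BW * AT)

with TEQ_pg in pg/m^3 (ng/m^3 x 1000), IR m^3/day, CF mg/pg (default 1e-9),
ED years, ET hours/day, EF days/year, CSF (mg/kg-day)^-1, BW kg, AT hours —
the units cancel to a dimensionless excess lifetime cancer probability.

In simulation, TEQ is lognormal, ET normal (truncated to [0, 24]), CSF
lognormal (GM 3.14, GSD 1.80 by default), and BW normal for children but a
point value for adults.  The model object runs both simulations in a single
pass over shared input draws so DI and ILCR are rank-consistent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .congeners import PopulationStratum
from .distributions import (
    LognormalSpec,
    NormalSpec,
    fit_lognormal,
    sample,
    substream,
)

__all__ = [
    "DEFAULT_CSF",
    "PopulationGroup",
    "RiskCategory",
    "RiskModel",
    "RiskSimResult",
    "simulate_di",
    "simulate_ilcr",
    "percentile_95",
    "classify_risk",
    "default_population_groups",
    "HOURS_PER_DAY",
    "NG_TO_PG",
    "DEFAULT_CF_MG_PER_PG",
    "ACCEPTABLE_BOUND",
    "CONCERN_BOUND",
]

# Unit constants of the intake/risk formulas, kept in one place.
HOURS_PER_DAY = 24.0
NG_TO_PG = 1000.0          # TEQ is carried in ng/m^3; the risk formula uses pg/m^3
DEFAULT_CF_MG_PER_PG = 1e-9

#: Inhalation cancer slope factor of BaP: lognormal with geometric mean 3.14
#: (mg/kg-day)^-1 and geometric SD 1.80.
DEFAULT_CSF = LognormalSpec(mu=math.log(3.14), sigma=math.log(1.80))

ACCEPTABLE_BOUND = 1e-6
CONCERN_BOUND = 1e-4


@dataclass(frozen=True)
class PopulationGroup:
    """Full exposure-factor set for one population stratum."""

    stratum: PopulationStratum
    ir_m3_day: float
    et: NormalSpec
    bw_kg: float | NormalSpec
    ed_years: float
    ef_days_year: float
    at_hours: float
    cf_mg_per_pg: float = DEFAULT_CF_MG_PER_PG
    csf: LognormalSpec = DEFAULT_CSF

    def __post_init__(self) -> None:
        if self.ir_m3_day <= 0:
            raise ValueError("inhalation rate must be positive")
        # 24 itself is allowed: the full-day exposure comparison case
        if not 0 < self.et.mean <= 24:
            raise ValueError("exposure-time mean must lie in (0, 24] h/day")
        bw_mean = self.bw_kg.mean if isinstance(self.bw_kg, NormalSpec) else self.bw_kg
        if bw_mean <= 0:
            raise ValueError("body weight must be positive")
        if self.ed_years <= 0 or self.ef_days_year <= 0 or self.at_hours <= 0:
            raise ValueError("ED, EF and AT must be positive")
        if self.ef_days_year > 366:
            raise ValueError("exposure frequency cannot exceed 366 days/year")
        if self.cf_mg_per_pg <= 0:
            raise ValueError("conversion factor must be positive")

    @classmethod
    def with_at_years(cls, *, at_years: float, **kwargs) -> "PopulationGroup":
        """Construct with averaging time given in years, converted to hours
        explicitly (365 days/year x 24 h/day)."""
        return cls(at_hours=at_years * 365.0 * HOURS_PER_DAY, **kwargs)

    @property
    def bw_is_stochastic(self) -> bool:
        return isinstance(self.bw_kg, NormalSpec) and self.bw_kg.sd > 0


class RiskCategory(str, enum.Enum):
    """Regulatory risk band of an ILCR value."""

    ACCEPTABLE = "acceptable"   # < 1e-6
    POTENTIAL = "potential"     # 1e-6 .. 1e-4 (boundaries inclusive)
    CONCERN = "concern"         # > 1e-4


def classify_risk(ilcr_value: float) -> RiskCategory:
    """Classify an ILCR against the 1e-6 / 1e-4 regulatory bounds.

    The boundaries themselves belong to the 'potential' band.
    """
    if ilcr_value < 0:
        raise ValueError("ILCR cannot be negative")
    if ilcr_value < ACCEPTABLE_BOUND:
        return RiskCategory.ACCEPTABLE
    if ilcr_value <= CONCERN_BOUND:
        return RiskCategory.POTENTIAL
    return RiskCategory.CONCERN


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskSimResult:
    """Monte-Carlo sample matrix of one DI/ILCR simulation.

    ``draws`` retains the per-iteration input samples (teq, et, csf, bw) so
    that sensitivity analysis can be run after the fact; ``di`` and ``ilcr``
    are the per-iteration outputs.  ``kind`` selects which output the scalar
    summaries describe.
    """

    draws: pd.DataFrame
    di: np.ndarray
    ilcr: np.ndarray
    n_iterations: int
    seed: int
    group: PopulationGroup
    teq: LognormalSpec
    kind: str = "ilcr"

    @property
    def samples(self) -> np.ndarray:
        return self.ilcr if self.kind == "ilcr" else self.di

    # type-7 (linear interpolation) sample quantiles throughout: the 95th
    # percentile is the headline statistic and must be stable across runs.
    def quantile(self, p: float) -> float:
        return float(np.percentile(self.samples, 100.0 * p))

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    @property
    def q1(self) -> float:
        return self.quantile(0.25)

    @property
    def q3(self) -> float:
        return self.quantile(0.75)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def p95(self) -> float:
        return self.quantile(0.95)

    def classify(self) -> RiskCategory:
        """Risk band of the 95th-percentile ILCR."""
        return classify_risk(float(np.percentile(self.ilcr, 95.0)))

    def as_kind(self, kind: str) -> "RiskSimResult":
        if kind not in ("di", "ilcr"):
            raise ValueError("kind must be 'di' or 'ilcr'")
        return replace(self, kind=kind)

    def sensitivity(self, transform: str = "none", inputs: list[str] | None = None):
        """Partial-correlation sensitivity of ILCR on its stochastic inputs.

        By default TEQ, ET and CSF enter for every group and BW joins only
        when the group draws it per iteration (children)."""
        from .sensitivity import partial_correlations

        if inputs is None:
            inputs = ["teq", "et", "csf"]
            if self.group.bw_is_stochastic:
                inputs.append("bw")
        return partial_correlations(self, inputs=inputs, transform=transform)

    def summary(self) -> pd.DataFrame:
        """One-row summary table: median, quartiles, IQR, mean, 95th
        percentile and the risk band (for ILCR results)."""
        s = self.stratum_labels()
        row = {
            **s,
            "output": self.kind,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "iqr": self.iqr,
            "mean": float(self.samples.mean()),
            "p95": self.p95,
        }
        if self.kind == "ilcr":
            row["risk_band"] = self.classify().value
        return pd.DataFrame([row])

    def stratum_labels(self) -> dict:
        st = self.group.stratum
        return {"city": st.city, "age_group": st.age_group, "gender": st.gender}

    def plot_cumulative(self, ax=None):
        from .plotting import plot_cumulative

        return plot_cumulative(self, ax=ax)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class RiskModel:
    """Inhalation risk model for one population group exposed to a lognormal
    BaP-TEQ concentration.

    Parameters
    ----------
    teq : LognormalSpec
        BaP-equivalent concentration (ng/m^3).
    group : PopulationGroup
        Exposure-factor set (IR, ET, BW, ED, EF, CF, AT, CSF).

    ``fit(n_iterations, seed)`` runs the Monte-Carlo simulation and returns a
    :class:`RiskSimResult`.
    """

    def __init__(self, teq: LognormalSpec, group: PopulationGroup):
        if not isinstance(teq, LognormalSpec):
            raise TypeError("teq must be a LognormalSpec")
        self.teq = teq
        self.group = group

    @classmethod
    def from_teq_series(
        cls, teq_values: Sequence[float], group: PopulationGroup, method: str = "mle"
    ) -> "RiskModel":
        """Build from a raw TEQ series (log-scale MLE fit by default)."""
        return cls(fit_lognormal(np.asarray(teq_values, float), method=method), group)

    @classmethod
    def from_teq_moments(
        cls, mean: float, sd: float, group: PopulationGroup
    ) -> "RiskModel":
        """Build from a reported arithmetic mean +/- SD (moment matching)."""
        from .distributions import lognormal_from_moments

        return cls(lognormal_from_moments(mean, sd), group)

    def fit(self, n_iterations: int = 10_000, seed: int = 0) -> RiskSimResult:
        """Run the Monte-Carlo simulation.

        Each variable draws from its own named substream of ``seed``; BW is
        drawn per iteration only when the group declares it stochastic
        (children), otherwise held at its point value.
        """
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        g = self.group
        n = int(n_iterations)
        teq_d = sample(self.teq, n, substream(seed, "teq"))
        et_d = sample(g.et, n, substream(seed, "et"))
        csf_d = sample(g.csf, n, substream(seed, "csf"))
        if isinstance(g.bw_kg, NormalSpec):
            bw_d = sample(g.bw_kg, n, substream(seed, "bw"))
        else:
            bw_d = np.full(n, float(g.bw_kg))

        di = teq_d * g.ir_m3_day * et_d / HOURS_PER_DAY
        ilcr = (
            teq_d * NG_TO_PG
            * g.ir_m3_day
            * g.cf_mg_per_pg
            * g.ed_years
            * et_d
            * g.ef_days_year
            * csf_d
            / (bw_d * g.at_hours)
        )
        draws = pd.DataFrame({"teq": teq_d, "et": et_d, "csf": csf_d, "bw": bw_d})
        return RiskSimResult(
            draws=draws,
            di=di,
            ilcr=ilcr,
            n_iterations=n,
            seed=int(seed),
            group=g,
            teq=self.teq,
        )


def simulate_di(
    teq: LognormalSpec, group: PopulationGroup, n: int = 10_000, seed: int = 0
) -> RiskSimResult:
    """Monte-Carlo daily intake (ng/day); summaries describe DI."""
    return RiskModel(teq, group).fit(n, seed).as_kind("di")


def simulate_ilcr(
    teq: LognormalSpec, group: PopulationGroup, n: int = 10_000, seed: int = 0
) -> RiskSimResult:
    """Monte-Carlo incremental lifetime cancer risk (dimensionless)."""
    return RiskModel(teq, group).fit(n, seed).as_kind("ilcr")


def percentile_95(result: RiskSimResult) -> float:
    """Type-7 sample 95th percentile of the result's primary samples."""
    if result.samples.size < 2:
        raise ValueError("need at least 2 samples for a percentile")
    return result.p95


# ---------------------------------------------------------------------------
# Default exposure factors
# ---------------------------------------------------------------------------

def default_population_groups() -> dict[PopulationStratum, PopulationGroup]:
    """Documented placeholder exposure factors per city x age x gender.

    Inhalation rates and body weights follow Chinese exposure-handbook-like
    values; exposure times come from the default survey designs.  These are
    explicit stand-ins for site-specific survey data — analyses of real
    measurements must supply their own population config.
    """
    from .synthetic import _ADULT_BW, _CHILD_BW, _SURVEY_PARAMS, _child_bw, _et

    ir = {("adult", "male"): 15.0, ("adult", "female"): 12.1,
          ("child", "male"): 9.5, ("child", "female"): 8.8}
    ed = {"adult": 70.0, "child": 10.0}
    at_hours = 70.0 * 365.0 * HOURS_PER_DAY

    groups: dict[PopulationStratum, PopulationGroup] = {}
    for city, params in _SURVEY_PARAMS.items():
        for (age, gender), (m, s) in params.items():
            if age == "adult":
                bw: float | NormalSpec = _ADULT_BW[gender]
            else:
                bw = _child_bw(*_CHILD_BW[gender])
            st = PopulationStratum(city, age, gender)
            groups[st] = PopulationGroup(
                stratum=st,
                ir_m3_day=ir[(age, gender)],
                et=_et(m, s),
                bw_kg=bw,
                ed_years=ed[age],
                ef_days_year=365.0,
                at_hours=at_hours,
            )
        # gender-pooled ("total") strata: midpoint parameters
        for age in ("adult", "child"):
            male = groups[PopulationStratum(city, age, "male")]
            female = groups[PopulationStratum(city, age, "female")]
            et = NormalSpec(
                0.5 * (male.et.mean + female.et.mean),
                0.5 * (male.et.sd + female.et.sd),
                lower=0.0,
                upper=24.0,
            )
            if isinstance(male.bw_kg, NormalSpec):
                bw = NormalSpec(
                    0.5 * (male.bw_kg.mean + female.bw_kg.mean),
                    0.5 * (male.bw_kg.sd + female.bw_kg.sd),
                    lower=male.bw_kg.lower,
                    upper=male.bw_kg.upper,
                )
            else:
                bw = 0.5 * (male.bw_kg + female.bw_kg)
            st = PopulationStratum(city, age, "total")
            groups[st] = PopulationGroup(
                stratum=st,
                ir_m3_day=0.5 * (male.ir_m3_day + female.ir_m3_day),
                et=et,
                bw_kg=bw,
                ed_years=male.ed_years,
                ef_days_year=male.ef_days_year,
                at_hours=male.at_hours,
            )
    return groups
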