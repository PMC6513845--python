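"""Sensitivity and uncertainty analysis of the ILCR simulation.

Sensitivity: the partial correlation between each stochastic input (TEQ, ET,
CSF, and BW for children) and the output ILCR, controlling linearly for the
remaining inputs.  Because ILCR is a product of its inputs, TEQ/ET/CSF act
positively and BW negatively.

Uncertainty: a two-dimensional Monte-Carlo analysis over the unknown upper
truncation of the cancer-slope-factor distribution.  The outer loop draws
100 truncation multipliers k ~ Uniform(2, 4) by Latin hypercube sampling;
each k truncates the CSF lognormal at exp(ln GM + k ln GSD); the inner loop
(10,000 iterations, common random numbers across the outer loop) yields the
95th-percentile ILCR, and the envelope reports the 2.5th-97.5th percentile
interval of the outer values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import LognormalSpec, UniformSpec, lhs_uniform, substream
from .risk import PopulationGroup, RiskModel, RiskSimResult

__all__ = [
    "SensitivityResult",
    "UncertaintyEnvelope",
    "partial_correlations",
    "two_dim_mca",
]

_TRANSFORMS = ("none", "rank", "log")


@dataclass(frozen=True)
class SensitivityResult:
    """Partial correlation coefficient of each input with ILCR (NaN where an
    input was held constant in the simulation)."""

    coefficients: pd.Series
    transform: str
    n_iterations: int

    def __getitem__(self, name: str) -> float:
        return float(self.coefficients[name])

    def summary(self) -> pd.DataFrame:
        out = self.coefficients.rename("partial_correlation").to_frame()
        out["transform"] = self.transform
        out["n_iterations"] = self.n_iterations
        return out.reset_index(names="input")


def _partial_corr(x: np.ndarray, y: np.ndarray, controls: np.ndarray) -> float:
    """Pearson correlation of x and y after regressing both on the controls
    (with intercept)."""
    design = np.column_stack([np.ones(len(x)), controls]) if controls.size else np.ones((len(x), 1))
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan")
    return float(np.clip((rx @ ry) / denom, -1.0, 1.0))


def partial_correlations(
    sim: RiskSimResult,
    inputs: list[str] | None = None,
    transform: str = "none",
) -> SensitivityResult:
    """Partial correlation of each retained input draw with the ILCR samples.

    ``inputs`` defaults to every stochastic column of ``sim.draws`` (constant
    columns get NaN with a warning and never act as controls).  ``transform``
    applies to inputs and output alike: 'none' (raw), 'rank', or 'log'.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}")
    draws = sim.draws
    names = list(inputs) if inputs is not None else list(draws.columns)
    unknown = [n for n in names if n not in draws.columns]
    if unknown:
        raise KeyError(f"inputs not retained in the simulation: {unknown}")
    n = len(draws)
    if n < len(names) + 3:
        raise ValueError("need at least 3 more iterations than inputs")

    cols = {name: draws[name].to_numpy(float) for name in names}
    y = sim.ilcr.astype(float)

    constant = {name for name, v in cols.items() if np.ptp(v) == 0}
    if constant:
        warnings.warn(
            f"constant input column(s) {sorted(constant)}: coefficient undefined"
        )

    def xform(v: np.ndarray) -> np.ndarray:
        if transform == "rank":
            return pd.Series(v).rank().to_numpy(float)
        if transform == "log":
            if np.any(v <= 0):
                raise ValueError("log transform requires positive samples")
            return np.log(v)
        return v

    yt = xform(y)
    coeffs = {}
    for name in names:
        if name in constant:
            coeffs[name] = float("nan")
            continue
        others = [
            cols[o] for o in names if o != name and o not in constant
        ]
        controls = (
            np.column_stack([xform(o) for o in others]) if others else np.empty((n, 0))
        )
        coeffs[name] = _partial_corr(xform(cols[name]), yt, controls)

    return SensitivityResult(
        coefficients=pd.Series(coeffs, name="partial_correlation"),
        transform=transform,
        n_iterations=n,
    )


# ---------------------------------------------------------------------------
# Two-dimensional Monte-Carlo uncertainty analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertaintyEnvelope:
    """Outer-loop collection of 95th-percentile ILCR values.

    ``ci`` is the 2.5th-97.5th percentile interval of the ``n_outer`` values:
    the 95% confidence interval for the 95th ILCR induced by not knowing the
    CSF truncation point.
    """

    k_values: np.ndarray
    p95_values: np.ndarray
    n_outer: int
    n_inner: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_outer < 2:
            raise ValueError("n_outer must be >= 2")

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.p95_values, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def ci_width(self) -> float:
        lo, hi = self.ci
        return hi - lo

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame(
            [
                {
                    "n_outer": self.n_outer,
                    "n_inner": self.n_inner,
                    "seed": self.seed,
                    "p95_median": float(np.median(self.p95_values)),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "ci_width": hi - lo,
                }
            ]
        )


def two_dim_mca(
    teq: LognormalSpec,
    group: PopulationGroup,
    k_range: UniformSpec = UniformSpec(2.0, 4.0),
    n_outer: int = 100,
    n_inner: int = 10_000,
    seed: int = 0,
) -> UncertaintyEnvelope:
    """Two-dimensional Monte-Carlo analysis of the CSF truncation parameter.

    The outer loop (uncertainty) draws ``n_outer`` multipliers k from
    ``k_range`` by Latin hypercube sampling; for each, the CSF lognormal is
    truncated at exp(ln GM + k ln GSD) and the inner loop (variability,
    ``n_inner`` iterations) computes the 95th-percentile ILCR.  All outer
    iterations share the same inner-loop substreams (common random numbers),
    so the envelope isolates truncation uncertainty from inner-loop noise.
    """
    if n_outer < 2:
        raise ValueError("n_outer must be >= 2")
    ks = lhs_uniform(k_range, n_outer, substream(seed, "outer"))
    p95s = np.empty(n_outer)
    for i, k in enumerate(ks):
        trunc_group = _with_truncated_csf(group, float(k))
        res = RiskModel(teq, trunc_group).fit(n_inner, seed)
        p95s[i] = float(np.percentile(res.ilcr, 95.0))
    return UncertaintyEnvelope(
        k_values=ks,
        p95_values=p95s,
        n_outer=int(n_outer),
        n_inner=int(n_inner),
        seed=int(seed),
    )


def _with_truncated_csf(group: PopulationGroup, k: float) -> PopulationGroup:
    from dataclasses import replace

    return replace(group, csf=group.csf.truncated(k))
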