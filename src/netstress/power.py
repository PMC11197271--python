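"""Power analysis for the 2x2 strength design.

Three effect-size columns, one per effect of the repeated-measures GLM, each
mapped to the t-test that the 2x2 design reduces to:

* stress main effect  -> one-sample (paired) t on all N difference scores;
  noncentrality delta = d * sqrt(N), df = N - 1.
* group main effect   -> two-sample t on per-subject two-scan averages.
  Averaging two uncorrelated scans halves the variance, so a Cohen's d on
  the single-scan scale inflates by sqrt(2):
  delta = d * sqrt(2) * sqrt(n1 n2 / (n1 + n2)), df = n1 + n2 - 2.
* interaction         -> two-sample t on difference scores;
  delta = d * sqrt(n1 n2 / (n1 + n2)), df = n1 + n2 - 2.

The zero between-scan correlation assumption behind the sqrt(2) factor is
explicit and configurable via ``scan_correlation``.  Power is evaluated
through the noncentral t distribution (two-tailed); a normal-approximation
mode is provided as well, since published power tables are often computed
that way.  ``mdes`` inverts ``power_of`` by monotone bracketing to 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = ["DESIGNS", "PowerQuery", "PowerResult", "power_of", "mdes", "power_table"]

DESIGNS = ("paired_within", "between_on_averages", "between_on_differences")

#: Effect labels of the 2x2 GLM mapped to their reduced t-test designs.
EFFECT_DESIGNS = {
    "stress": "paired_within",
    "group": "between_on_averages",
    "interaction": "between_on_differences",
}


@dataclass(frozen=True)
class PowerQuery:
    """A power (given d) or minimum-detectable-effect (given power) question."""

    design: str
    n1: int
    n2: Optional[int] = None
    alpha: float = 0.05
    d: Optional[float] = None
    target_power: Optional[float] = None
    approx: str = "nct"  # "nct" (exact noncentral t) or "normal"
    scan_correlation: float = 0.0  # between-scan correlation for averages

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.design != "paired_within" and self.n2 is None:
            raise ValueError(f"{self.design} needs two group sizes")
        if self.n1 < 2 or (self.n2 is not None and self.n2 < 2):
            raise ValueError("group sizes must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if (self.d is None) == (self.target_power is None):
            raise ValueError("supply exactly one of d / target_power")
        if self.d is not None and self.d <= 0:
            raise ValueError("d must be positive")
        if self.target_power is not None and not (self.alpha < self.target_power < 1.0):
            raise ValueError("target_power must lie in (alpha, 1)")
        if self.approx not in ("nct", "normal"):
            raise ValueError("approx must be 'nct' or 'normal'")
        if not (-1.0 < self.scan_correlation < 1.0):
            raise ValueError("scan_correlation must lie in (-1, 1)")


@dataclass(frozen=True)
class PowerResult:
    d: float
    power: float
    noncentrality: float
    df: int
    design: str
    alpha: float


def _delta_df(q: PowerQuery, d: float) -> tuple[float, int]:
    if q.design == "paired_within":
        return d * np.sqrt(q.n1), q.n1 - 1
    ne = np.sqrt(q.n1 * q.n2 / (q.n1 + q.n2))
    df = q.n1 + q.n2 - 2
    if q.design == "between_on_differences":
        return d * ne, df
    # averaging two scans with correlation rho scales the SD by
    # sqrt((1 + rho) / 2); rho = 0 gives the sqrt(2) inflation of d
    scale = np.sqrt(2.0 / (1.0 + q.scan_correlation))
    return d * scale * ne, df


def _two_tailed_power(delta: float, df: int, alpha: float, approx: str) -> float:
    if approx == "normal":
        zc = stats.norm.ppf(1.0 - alpha / 2.0)
        return float(stats.norm.sf(zc - delta) + stats.norm.cdf(-zc - delta))
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    hi = stats.nct.sf(tc, df, delta)
    lo = stats.nct.cdf(-tc, df, delta)
    if np.isnan(hi) or np.isnan(lo):  # extreme noncentrality: power is 1
        return 1.0
    return float(min(hi + lo, 1.0))


def power_of(q: PowerQuery) -> PowerResult:
    """Two-tailed power of the design's t-test at the query's effect size."""
    if q.d is None:
        raise ValueError("power_of needs a query with d set")
    delta, df = _delta_df(q, q.d)
    power = _two_tailed_power(delta, df, q.alpha, q.approx)
    return PowerResult(d=q.d, power=power, noncentrality=float(delta),
                       df=df, design=q.design, alpha=q.alpha)


def mdes(q: PowerQuery) -> PowerResult:
    """Minimum detectable Cohen's d reaching the target power (bisection)."""
    if q.target_power is None:
        raise ValueError("mdes needs a query with target_power set")

    def gap(d: float) -> float:
        delta, df = _delta_df(q, d)
        return _two_tailed_power(delta, df, q.alpha, q.approx) - q.target_power

    lo, hi = 1e-6, 10.0
    if gap(hi) < 0:
        raise ValueError("target power unreachable with d <= 10")
    d = float(optimize.brentq(gap, lo, hi, xtol=1e-8))
    delta, df = _delta_df(q, d)
    return PowerResult(d=d, power=q.target_power, noncentrality=float(delta),
                       df=df, design=q.design, alpha=q.alpha)


def power_table(
    n1: int = 28,
    n2: int = 24,
    powers: tuple[float, ...] = (0.80, 0.85, 0.90),
    alpha: float = 0.05,
    approx: str = "nct",
) -> "pd.DataFrame":
    """Minimum detectable Cohen's d per effect (columns) and power (rows).

    The stress column uses the combined sample (n1 + n2) as one paired group.
    """
    import pandas as pd

    rows = {}
    for p in powers:
        row = {}
        for effect, design in EFFECT_DESIGNS.items():
            if design == "paired_within":
                q = PowerQuery(design=design, n1=n1 + n2, alpha=alpha,
                               target_power=p, approx=approx)
            else:
                q = PowerQuery(design=design, n1=n1, n2=n2, alpha=alpha,
                               target_power=p, approx=approx)
            row[effect] = mdes(q).d
        rows[f"{p:.0%}"] = row
    return pd.DataFrame(rows).T[list(EFFECT_DESIGNS)]
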