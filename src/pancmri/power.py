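"""Sample-size estimation from reproducibility variance components.

Normal-approximation (z-based) formulas for detecting a shift delta at
two-sided significance alpha with a prescribed power:

* two independent groups (e.g. controls vs patients), per group::

      n = ceil( 2 * ((z_{1-alpha/2} + z_power) * sigma_between / delta)^2 )

  using the inter-individual SD; the total over both (equal) groups is also
  reported.
* within-subject (longitudinal) change::

      n = ceil( ((z_{1-alpha/2} + z_power) * sigma_within / delta)^2 )

  using the inter-assay SD, floored at 3 subjects.

delta is a stated percentage of the measure's grand mean.  An optional
iterative t-distribution refinement replaces the z quantiles with t
quantiles at the implied degrees of freedom until the size stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .repro import VarianceComponents, variance_components

__all__ = ["PowerRequest", "required_sample_size", "power_table"]

_MIN_WITHIN_SUBJECT_N = 3


@dataclass(frozen=True)
class PowerRequest:
    design: str  # "two_independent_groups" | "within_subject"
    power: float = 0.80
    percent_difference: float = 10.0
    alpha: float = 0.05
    use_t: bool = False

    def __post_init__(self) -> None:
        if self.design not in ("two_independent_groups", "within_subject"):
            raise ValueError(f"unknown design {self.design!r}")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.percent_difference <= 0:
            raise ValueError("percent_difference must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class SampleSize:
    n: int                  # per group (two-group) or subjects (within)
    total: int              # 2n for two-group designs, n otherwise
    degenerate: bool = False


def _z_n(sd: float, delta: float, power: float, alpha: float, two_group: bool) -> float:
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    base = (z * sd / delta) ** 2
    return 2 * base if two_group else base


def _t_refine(n0: int, sd: float, delta: float, power: float, alpha: float,
              two_group: bool) -> int:
    n = max(n0, 2)
    for _ in range(50):
        df = 2 * (n - 1) if two_group else n - 1
        if df < 1:
            df = 1
        t = sps.t.ppf(1 - alpha / 2, df) + sps.t.ppf(power, df)
        base = (t * sd / delta) ** 2
        new = math.ceil(2 * base if two_group else base)
        if new == n:
            return n
        n = new
    return n


def required_sample_size(components: VarianceComponents, request: PowerRequest) -> SampleSize:
    """Subjects needed to detect ``percent_difference`` % of the grand mean.

    Two-group designs use the inter-individual SD and report per-group and
    total counts; within-subject designs use the inter-assay SD with a floor
    of 3.  A zero relevant SD returns the floor flagged degenerate.
    """
    two_group = request.design == "two_independent_groups"
    sd = components.inter_individual_sd if two_group else components.inter_assay_sd
    delta = request.percent_difference / 100.0 * components.grand_mean
    if delta == 0:
        raise ValueError("grand mean is zero; percent difference has no scale")
    if sd == 0:
        floor = 2 if two_group else _MIN_WITHIN_SUBJECT_N
        return SampleSize(floor, 2 * floor if two_group else floor, degenerate=True)
    n = math.ceil(_z_n(sd, abs(delta), request.power, request.alpha, two_group))
    if request.use_t:
        n = _t_refine(n, sd, abs(delta), request.power, request.alpha, two_group)
    if not two_group:
        n = max(n, _MIN_WITHIN_SUBJECT_N)
    return SampleSize(n, 2 * n if two_group else n)


def power_table(
    table: pd.DataFrame,
    measures: list[str] | None = None,
    powers: tuple[float, ...] = (0.80, 0.90),
    percent_differences: tuple[float, ...] = (5.0, 10.0, 20.0),
    alpha: float = 0.05,
    use_t: bool = False,
) -> pd.DataFrame:
    """Sample-size grid (design x power x difference x measure) from a
    measure table, one row per cell; measures whose variance components
    cannot be computed are flagged rather than aborting the grid."""
    if measures is None:
        measures = sorted(table["measure"].unique())
    rows = []
    for measure in measures:
        try:
            comps = variance_components(table, measure)
        except Exception as exc:
            rows.append(dict(measure=measure, design="", power=np.nan,
                             percent_difference=np.nan, n=np.nan, total=np.nan,
                             note=f"insufficient data: {exc}"))
            continue
        for design in ("two_independent_groups", "within_subject"):
            for power in powers:
                for diff in percent_differences:
                    req = PowerRequest(design, power, diff, alpha, use_t)
                    size = required_sample_size(comps, req)
                    rows.append(dict(
                        measure=measure, design=design, power=power,
                        percent_difference=diff, n=size.n, total=size.total,
                        note="degenerate" if size.degenerate else "",
                    ))
    return pd.DataFrame(rows)
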