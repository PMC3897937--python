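"""Two-sample t-test power and sample-size calculations via the non-central t.

For a two-sided two-sample t-test with ``n`` subjects per group, true mean
difference ``delta`` and common standard deviation ``sd``, the test statistic
under the alternative follows a non-central t distribution with
``df = 2n - 2`` degrees of freedom and non-centrality parameter

    ncp = delta / (sd * sqrt(2 / n))

Power is the probability that |T'| exceeds the two-sided critical value
``t_{1-alpha/2, df}``.  No normal-approximation shortcut is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize
from scipy.stats import nct, t as t_dist

__all__ = ["PowerSpec", "t_power", "required_n"]

# hard cap for the sample-size search; beyond this the requested power is
# declared unreachable for the given effect size
N_CAP = 1_000_000


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sample t-test power calculation.

    delta : true between-group mean difference (same units as ``sd``)
    sd : common within-group standard deviation, > 0
    alpha : two-sided significance level, in (0, 1)
    power : target power (1 - beta), in (0, 1)
    n_per_group : per-group sample size, >= 2
    """

    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80
    n_per_group: int | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if self.n_per_group is not None and self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")


def _power_from_df_ncp(df: float, ncp: float, alpha: float) -> float:
    t_crit = t_dist.ppf(1 - alpha / 2, df)
    # sf on the upper tail avoids cancellation for large ncp
    return float(nct.sf(t_crit, df, ncp) + nct.cdf(-t_crit, df, ncp))


def t_power(
    n_per_group: float,
    delta: float,
    sd: float,
    alpha: float = 0.05,
    n2: float | None = None,
) -> float:
    """Power of a two-sided two-sample t-test.

    ``n_per_group`` may be fractional (used internally by the continuous
    sample-size solver).  With ``n2`` given, groups of size ``n_per_group``
    and ``n2`` are compared (df = n1 + n2 - 2); otherwise equal allocation
    is assumed.
    """
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_per_group < 2 or (n2 is not None and n2 < 2):
        raise ValueError("each group needs n >= 2")
    if n2 is None:
        df = 2 * n_per_group - 2
        se_factor = math.sqrt(2 / n_per_group)
    else:
        df = n_per_group + n2 - 2
        se_factor = math.sqrt(1 / n_per_group + 1 / n2)
    ncp = delta / (sd * se_factor)
    return _power_from_df_ncp(df, ncp, alpha)


def required_n(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    rounding: str = "nearest",
) -> int:
    """Per-group sample size for a two-sided two-sample t-test.

    Solves ``t_power(n, delta, sd, alpha) = power`` for real-valued ``n``
    (degrees of freedom ``2n - 2``), then converts to an integer:

    - ``rounding="nearest"`` (default): nearest integer to the continuous
      solution — the convention under which sample sizes are conventionally
      reported from solvers such as R's ``power.t.test``;
    - ``rounding="ceil"``: smallest integer ``n`` whose achieved power meets
      the target, i.e. a guaranteed bound (never smaller than "nearest").
    """
    if delta == 0:
        raise ValueError("delta must be nonzero to solve for a sample size")
    PowerSpec(delta=delta, sd=sd, alpha=alpha, power=power)  # validates
    if rounding not in ("nearest", "ceil"):
        raise ValueError(f"unknown rounding rule {rounding!r}")

    def gap(n: float) -> float:
        return t_power(n, delta, sd, alpha) - power

    if gap(2.0) >= 0:
        return 2
    hi = 4.0
    while gap(hi) < 0:
        hi *= 2
        if hi > N_CAP:
            raise ValueError(
                f"required n exceeds cap {N_CAP}: effect delta/sd="
                f"{delta / sd:.3g} too small for power {power}"
            )
    n_star = optimize.brentq(gap, hi / 2 if hi > 4 else 2.0, hi, xtol=1e-8)
    if rounding == "nearest":
        n_int = max(2, int(math.floor(n_star + 0.5)))
    else:
        n_int = max(2, int(math.ceil(n_star - 1e-9)))
        # guard against the continuous root landing a hair under an integer
        while t_power(n_int, delta, sd, alpha) < power - 1e-9:
            n_int += 1
    return n_int
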