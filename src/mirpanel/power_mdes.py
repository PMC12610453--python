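"""Post hoc power: representative dispersion, pi0, effective alpha, MDES.

The minimal detectable effect size (MDES) is the root in delta of the
two-sided noncentral-t power function at a stated alpha and power, using a
representative delta-Ct SD and the contrast's group sizes. Multiplicity is
handled two ways: a Bonferroni bound alpha/m and a BH-effective level
base_alpha * (1 - pi0), with pi0 estimated from the raw p-value distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from mirpanel.diffexpr import Contrast, DeltaCtTable

DF_POOLED = "pooled"
DF_WELCH_EQUAL = "welch_equal_variance"
_DF_CONVENTIONS = (DF_POOLED, DF_WELCH_EQUAL)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a post hoc sensitivity computation for one contrast."""

    n_a: int
    n_b: int
    sd: float
    m: int = 84
    base_alpha: float = 0.05
    power_levels: tuple[float, ...] = (0.80, 0.90)
    df_convention: str = DF_POOLED

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b) < 2:
            raise ValueError("group sizes must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0 < self.base_alpha < 1:
            raise ValueError("base_alpha must be in (0, 1)")
        if self.df_convention not in _DF_CONVENTIONS:
            raise ValueError(f"df_convention must be one of {_DF_CONVENTIONS}")
        object.__setattr__(self, "power_levels", tuple(self.power_levels))


def _degrees_of_freedom(n_a: int, n_b: int, convention: str) -> float:
    if convention == DF_POOLED:
        return float(n_a + n_b - 2)
    if convention == DF_WELCH_EQUAL:
        qa, qb = 1.0 / n_a, 1.0 / n_b
        return (qa + qb) ** 2 / (qa**2 / (n_a - 1) + qb**2 / (n_b - 1))
    raise ValueError(f"unknown df convention {convention!r}")


def representative_sd(dct: DeltaCtTable, contrast: Contrast) -> float:
    """Median across target assays of the two-group pooled delta-Ct SD."""
    a_frame = dct.dct.loc[list(contrast.group_a_ids)]
    b_frame = dct.dct.loc[list(contrast.group_b_ids)]
    pooled = []
    for assay in dct.target_assay_ids:
        a = a_frame[assay].dropna().to_numpy(dtype=float)
        b = b_frame[assay].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            continue
        na, nb = a.size, b.size
        s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        pooled.append(np.sqrt(s2))
    if not pooled:
        raise ValueError("no assay with >=2 values in each group")
    return float(np.median(pooled))


def estimate_pi0(
    p: Sequence[float],
    lam: float = 0.5,
    method: str = "fixed",
    floor: float | None = None,
) -> float:
    """Proportion of null hypotheses from the p-value distribution.

    ``fixed``: #{p > lam} / (m * (1 - lam)). ``smoother``: the fixed-lambda
    estimate averaged over a lambda grid 0.05..0.95. Clamped to
    [floor, 1] with floor defaulting to 1/m so downstream effective-alpha
    arithmetic never divides to zero.
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if floor is None:
        floor = 1.0 / m

    def _fixed(l: float) -> float:
        if not 0 < l < 1:
            raise ValueError("lambda must be in (0, 1)")
        return float(np.sum(p > l)) / (m * (1.0 - l))

    if method == "fixed":
        pi0 = _fixed(lam)
    elif method == "smoother":
        grid = np.arange(0.05, 0.96, 0.05)
        pi0 = float(np.mean([_fixed(l) for l in grid]))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return float(min(1.0, max(floor, pi0)))


def effective_alpha(pi0: float, base_alpha: float = 0.05, m: int = 84) -> float:
    """BH-effective per-test level base_alpha * (1 - pi0).

    Floored at base_alpha / m (the Bonferroni level) so a pi0 of 1 yields a
    usable, nonzero rejection region rather than zero.
    """
    if not 0 <= pi0 <= 1:
        raise ValueError("pi0 must be in [0, 1]")
    return max(base_alpha * (1.0 - pi0), base_alpha / m)


def power_two_sample_t(
    delta: float,
    sd: float,
    n_a: int,
    n_b: int,
    alpha: float,
    df_convention: str = DF_POOLED,
) -> float:
    """Two-sided power of a two-sample t-test at true difference ``delta``.

    Noncentrality delta / (sd * sqrt(1/n_a + 1/n_b)); df per convention
    (pooled: n_a + n_b - 2). At delta = 0 the rejection probability is alpha
    by construction. The far tail of the noncentral t is guarded against
    numerical NaN at large noncentrality, where its mass is negligible.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if min(n_a, n_b) < 2:
        raise ValueError("group sizes must be >= 2")
    if delta == 0:
        return float(alpha)
    df = _degrees_of_freedom(n_a, n_b, df_convention)
    ncp = delta / (sd * np.sqrt(1.0 / n_a + 1.0 / n_b))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)
    if np.isnan(upper):
        upper = 1.0 if ncp > t_crit else 0.0
    if np.isnan(lower):
        lower = 1.0 if -ncp > t_crit else 0.0
    return float(min(1.0, max(0.0, upper + lower)))


def mdes_solve(spec: PowerSpec, alpha: float, power: float) -> float:
    """Smallest |log2 effect| detectable at the stated alpha and power.

    Bracketed root of power(delta) - power on [1e-6, 20 * sd] (the bracket is
    doubled if needed), solved to well below 1e-6 log2 units.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")

    def objective(delta: float) -> float:
        return (
            power_two_sample_t(
                delta, spec.sd, spec.n_a, spec.n_b, alpha, spec.df_convention
            )
            - power
        )

    lo, hi = 1e-6, 20.0 * spec.sd
    if objective(lo) > 0:
        raise ValueError("power at the lower bracket already exceeds the target")
    tries = 0
    while objective(hi) < 0:
        hi *= 2.0
        tries += 1
        if tries > 20:
            raise ValueError("could not bracket the MDES root")
    return float(optimize.brentq(objective, lo, hi, xtol=1e-9))


def mdes_report(
    dct: DeltaCtTable,
    de_by_contrast: Mapping[str, pd.DataFrame],
    contrasts: Sequence[Contrast],
    base_alpha: float = 0.05,
    power_levels: Sequence[float] = (0.80, 0.90),
    sd_override: float | None = None,
    m_override: int | None = None,
    pi0_method: str = "fixed",
    pi0_lambda: float = 0.5,
    df_convention: str = DF_POOLED,
    curve_points: int = 81,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-contrast MDES table plus a sampled power-versus-effect-size curve.

    For each contrast: representative SD (unless overridden), pi0 from that
    contrast's raw p-values, Bonferroni and BH-effective alphas, and the MDES
    at each requested power level under both policies.
    """
    mdes_rows = []
    curve_rows = []
    for contrast in contrasts:
        de = de_by_contrast[contrast.name]
        tested = de[de["tested"]] if "tested" in de.columns else de
        raw_p = tested["p"].dropna().to_numpy(dtype=float)
        if raw_p.size == 0:
            raise ValueError(f"contrast {contrast.name!r}: no tested assays")
        m = m_override if m_override is not None else raw_p.size
        sd = sd_override if sd_override is not None else representative_sd(dct, contrast)
        pi0 = estimate_pi0(raw_p, lam=pi0_lambda, method=pi0_method)
        spec = PowerSpec(
            n_a=len(contrast.group_a_ids),
            n_b=len(contrast.group_b_ids),
            sd=sd,
            m=m,
            base_alpha=base_alpha,
            power_levels=tuple(power_levels),
            df_convention=df_convention,
        )
        policies = {
            "bonferroni": base_alpha / m,
            "bh_effective": effective_alpha(pi0, base_alpha, m),
        }
        for policy, alpha_used in policies.items():
            for power in power_levels:
                mdes = mdes_solve(spec, alpha_used, power)
                mdes_rows.append(
                    dict(
                        contrast=contrast.name,
                        alpha_policy=policy,
                        alpha_used=alpha_used,
                        pi0=pi0 if policy == "bh_effective" else np.nan,
                        sd=sd,
                        m=m,
                        power=power,
                        mdes_log2=mdes,
                        mdes_fold=float(2.0**mdes),
                    )
                )
            grid = np.linspace(0.0, 4.0 * sd, curve_points)
            for delta in grid:
                curve_rows.append(
                    dict(
                        contrast=contrast.name,
                        alpha_policy=policy,
                        delta_log2=float(delta),
                        power=power_two_sample_t(
                            float(delta), sd, spec.n_a, spec.n_b, alpha_used,
                            df_convention,
                        ),
                    )
                )
    return pd.DataFrame(mdes_rows), pd.DataFrame(curve_rows)
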