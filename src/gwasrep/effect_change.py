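"""Winner's-curse quantification: change in OR between discovery and
replication.

A single-predictor ordinary least squares model regresses the replication OR
on the discovery OR, with both ORs normalized above 1 and SNVs pooled across
traits.  The slope is read as a multiplicative change: a coefficient of 0.80
means a 20% decrease in OR between the two GWAS (``percent_change =
(slope - 1) * 100``, negative = shrinkage).  The fit can be restricted to
replicated SNVs or run on all discovery-significant SNVs, and to binary or
quantitative traits.

The percent-change reading of the slope is exact only for a model through
the origin, so a no-intercept variant is provided; with an intercept the
slope still measures the marginal OR change.  A log-OR option exists for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

SUBSETS = ("replicated_only", "all_significant")
TRAIT_SCOPES = ("all", "binary", "quantitative")


@dataclass(frozen=True)
class EffectChangeFit:
    """OLS slope of replication OR on discovery OR, as percent change."""

    subset: str
    trait_scope: str
    coefficient: float
    coef_se: float
    coef_ci_low: float
    coef_ci_high: float
    percent_change: float
    n_snvs: int
    intercept: float | None  # None for the through-origin fit
    log_scale: bool = False

    def as_dict(self) -> dict:
        return {
            "subset": self.subset,
            "trait_scope": self.trait_scope,
            "n_snvs": self.n_snvs,
            "coefficient": self.coefficient,
            "coef_se": self.coef_se,
            "coef_ci_low": self.coef_ci_low,
            "coef_ci_high": self.coef_ci_high,
            "percent_change": self.percent_change,
            "intercept": self.intercept,
            "log_scale": self.log_scale,
        }


def fit_effect_change(
    snvs: pd.DataFrame,
    calls: pd.DataFrame,
    subset: str = "replicated_only",
    trait_scope: str = "all",
    with_intercept: bool = True,
    log_scale: bool = False,
) -> EffectChangeFit:
    """Fit the effect-size-change regression on one SNV subset.

    ``snvs`` is a harmonized table (possibly concatenated across traits),
    ``calls`` the matching replication calls.  Raises ``ValueError`` for
    subsets of fewer than 3 SNVs or a constant predictor.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}")
    if trait_scope not in TRAIT_SCOPES:
        raise ValueError(f"unknown trait_scope {trait_scope!r}")

    df = snvs.merge(
        calls[["variant_id", "trait_name", "significant_discovery", "replicated"]],
        on=["variant_id", "trait_name"],
        how="inner",
        validate="one_to_one",
    )
    df = df[df["significant_discovery"]]
    if subset == "replicated_only":
        df = df[df["replicated"]]
    if trait_scope != "all":
        df = df[df["trait_type"] == trait_scope]

    x = df["or_discovery_norm"].to_numpy(dtype=float)
    y = df["or_replication_norm"].to_numpy(dtype=float)
    if log_scale:
        x, y = np.log(x), np.log(y)
    if len(x) < 3:
        raise ValueError(f"subset {subset!r}/{trait_scope!r} has {len(x)} SNVs; need >= 3")
    if np.ptp(x) == 0.0:
        raise ValueError("discovery OR has zero variance in this subset")

    X = sm.add_constant(x) if with_intercept else x[:, None]
    res = sm.OLS(y, X).fit()
    slope_idx = 1 if with_intercept else 0
    slope = float(res.params[slope_idx])
    ci = res.conf_int(alpha=0.05)
    return EffectChangeFit(
        subset=subset,
        trait_scope=trait_scope,
        coefficient=slope,
        coef_se=float(res.bse[slope_idx]),
        coef_ci_low=float(ci[slope_idx][0]),
        coef_ci_high=float(ci[slope_idx][1]),
        percent_change=(slope - 1.0) * 100.0,
        n_snvs=len(x),
        intercept=float(res.params[0]) if with_intercept else None,
        log_scale=log_scale,
    )


def effect_change_table(
    snvs: pd.DataFrame,
    calls: pd.DataFrame,
    with_intercept: bool = True,
) -> pd.DataFrame:
    """All subset x trait-scope fits that are estimable, as one table."""
    rows = []
    present = set(snvs["trait_type"].unique())
    for subset in SUBSETS:
        for scope in TRAIT_SCOPES:
            if scope != "all" and scope not in present:
                continue
            try:
                fit = fit_effect_change(snvs, calls, subset, scope, with_intercept)
            except ValueError:
                continue
            rows.append(fit.as_dict())
    return pd.DataFrame(rows)
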