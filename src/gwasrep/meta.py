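"""Pooling of per-trait replication rates.

Two fixed-effects pooling routes are provided:

* :func:`pool_counts` — sum numerators and denominators across traits and
  put a Wilson interval on the pooled counts.  This is the default route:
  with every SNV weighted equally it is the fixed-effects answer for a
  common underlying rate, and it is well defined for a single trait.
* :func:`iv_fixed` — classical inverse-variance fixed-effects pooling of the
  per-trait proportions, on the proportion scale or the logit scale (with a
  0.5 continuity correction, flagged, for degenerate members).  The two
  routes agree closely because inverse-variance weights are ~ n/(p(1-p)).

No heterogeneity model is fitted: the pooling is fixed-effects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .replicate import RateEstimate, wilson_ci


@dataclass(frozen=True)
class PooledRate:
    """A pooled replication rate across member traits."""

    stratum_label: str
    member_traits: tuple[str, ...]
    pooled_rate: float
    ci_low: float
    ci_high: float
    method: str  # "pooled_counts" | "iv_fixed"
    k: int | None = None
    n: int | None = None
    weights: dict[str, float] | None = None
    continuity_corrected: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum_label,
            "method": self.method,
            "k_replicated": self.k,
            "n_eligible": self.n,
            "rate": self.pooled_rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_traits": len(self.member_traits),
        }


def pool_counts(estimates: list[RateEstimate], label: str = "pooled") -> PooledRate:
    """Pool by summing counts; Wilson 95% CI on the pooled counts."""
    if not estimates:
        raise ValueError("no estimates to pool")
    k = sum(e.k for e in estimates)
    n = sum(e.n for e in estimates)
    if n == 0:
        raise ValueError("pooled denominator is zero")
    lo, hi = wilson_ci(k, n)
    return PooledRate(
        stratum_label=label,
        member_traits=tuple(e.stratum_label for e in estimates),
        pooled_rate=k / n,
        ci_low=lo,
        ci_high=hi,
        method="pooled_counts",
        k=k,
        n=n,
    )


def iv_fixed(
    estimates: list[RateEstimate], scale: str = "proportion", label: str = "pooled"
) -> PooledRate:
    """Inverse-variance fixed-effects pooling of proportions.

    Members with k = 0 or k = n get the Haldane–Anscombe continuity
    correction (k + 0.5, n + 1) before variance calculation; their stratum
    labels are reported in ``continuity_corrected``.  Requires >= 2 members
    (a single estimate needs no pooling — use :func:`pool_counts`).
    """
    if scale not in ("proportion", "logit"):
        raise ValueError(f"unknown scale {scale!r}")
    if len(estimates) < 2:
        raise ValueError("iv_fixed needs >= 2 estimates; use pool_counts for a single stratum")

    thetas, variances, corrected = [], [], []
    for e in estimates:
        k, n = e.k, e.n
        if k == 0 or k == n:
            k, n = k + 0.5, n + 1.0
            corrected.append(e.stratum_label)
        p = k / n
        if scale == "proportion":
            thetas.append(p)
            variances.append(p * (1.0 - p) / n)
        else:
            thetas.append(np.log(p / (1.0 - p)))
            variances.append(1.0 / (n * p * (1.0 - p)))

    w = 1.0 / np.asarray(variances)
    theta = float(np.sum(w * np.asarray(thetas)) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = stats.norm.ppf(0.975)
    lo, hi = theta - z * se, theta + z * se
    if scale == "logit":
        theta, lo, hi = (1.0 / (1.0 + np.exp(-x)) for x in (theta, lo, hi))
    lo, hi = max(0.0, float(lo)), min(1.0, float(hi))

    w_norm = w / np.sum(w)
    return PooledRate(
        stratum_label=label,
        member_traits=tuple(e.stratum_label for e in estimates),
        pooled_rate=float(theta),
        ci_low=lo,
        ci_high=hi,
        method="iv_fixed",
        weights={e.stratum_label: float(wi) for e, wi in zip(estimates, w_norm)},
        continuity_corrected=tuple(corrected),
    )
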