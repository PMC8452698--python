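"""Replication classification and stratified replication rates.

A discovery-significant SNV (P < 5e-8 by default) counts as replicated when
it is also significant in the replication cohort *and* its effect points the
same way in both — both aligned ORs above 1 or both below 1, evaluated on
the pre-normalization scale.  An OR of exactly 1 in either cohort is
incongruent (strict inequalities).

Rates are simple proportions k/n with Wilson score 95% intervals, reported
per trait and within discovery P-value and odds-ratio bins.  Two sensitivity
analyses re-run the classification with (a) a lenient threshold applied to
both cohorts and (b) a per-trait Bonferroni replication threshold 0.05/N,
where N is that trait's count of discovery-significant SNVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

GENOME_WIDE_ALPHA = 5e-8
DEFAULT_LENIENT_ALPHA = 1e-6

#: discovery P-value bin edges, descending; last bin is "< 5e-11"
P_BIN_EDGES = (5e-8, 5e-9, 5e-10, 5e-11)
P_BIN_LABELS = ("5e-8 to 5e-9", "5e-9 to 5e-10", "5e-10 to 5e-11", "< 5e-11")

#: normalized discovery OR bin edges, ascending; last bin is "> 1.4"
OR_BIN_EDGES = (1.0, 1.05, 1.1, 1.15, 1.2, 1.3, 1.4, np.inf)
OR_BIN_LABELS = ("1-1.05", "1.05-1.1", "1.1-1.15", "1.15-1.2", "1.2-1.3", "1.3-1.4", "> 1.4")


@dataclass(frozen=True)
class RateEstimate:
    """A replication proportion with Wilson 95% CI for one stratum."""

    stratum_label: str
    k: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    ci_method: str = "wilson"

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum_label,
            "k_replicated": self.k,
            "n_eligible": self.n,
            "rate": self.rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
        }


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    return float(lo), float(hi)


def call_replication(
    snvs: pd.DataFrame,
    alpha_discovery: float = GENOME_WIDE_ALPHA,
    alpha_replication: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Classify every harmonized SNV.

    Returns one row per input SNV with ``significant_discovery``,
    ``replicated`` and, for eligible non-replicated SNVs, a ``failure_reason``
    in {``not_significant_replication``, ``direction_incongruent``, ``both``}.
    """
    sig_d = snvs["p_discovery"].to_numpy() < alpha_discovery
    sig_r = snvs["p_replication"].to_numpy() < alpha_replication
    congruent = (snvs["or_discovery"].to_numpy() - 1.0) * (
        snvs["or_replication"].to_numpy() - 1.0
    ) > 0.0
    replicated = sig_d & sig_r & congruent

    reason = np.full(len(snvs), "", dtype=object)
    failed = sig_d & ~replicated
    reason[failed & ~sig_r & congruent] = "not_significant_replication"
    reason[failed & sig_r & ~congruent] = "direction_incongruent"
    reason[failed & ~sig_r & ~congruent] = "both"

    return pd.DataFrame(
        {
            "variant_id": snvs["variant_id"].to_numpy(),
            "trait_name": snvs["trait_name"].to_numpy(),
            "significant_discovery": sig_d,
            "replicated": replicated,
            "failure_reason": reason,
        }
    )


def rate(calls: pd.DataFrame, label: str, conf: float = 0.95) -> RateEstimate:
    """Replication proportion among discovery-significant SNVs."""
    eligible = calls[calls["significant_discovery"]]
    return rate_from_counts(int(eligible["replicated"].sum()), len(eligible), label, conf)


def rate_from_counts(k: int, n: int, label: str, conf: float = 0.95) -> RateEstimate:
    """Build a :class:`RateEstimate` directly from counts."""
    if n < 1:
        raise ValueError(f"empty stratum {label!r}")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lo, hi = wilson_ci(k, n, conf)
    return RateEstimate(stratum_label=label, k=k, n=n, rate=k / n, ci_low=lo, ci_high=hi)


def _binned_rates(values, replicated, masks_labels) -> pd.DataFrame:
    rows = []
    for mask, label in masks_labels:
        n = int(mask.sum())
        if n == 0:
            rows.append(
                {"stratum": label, "k_replicated": 0, "n_eligible": 0,
                 "rate": np.nan, "ci_low": np.nan, "ci_high": np.nan, "ci_method": "wilson"}
            )
            continue
        rows.append(rate_from_counts(int(replicated[mask].sum()), n, label).as_dict())
    return pd.DataFrame(rows)


def bin_by_p(
    snvs: pd.DataFrame, calls: pd.DataFrame, edges: tuple[float, ...] = P_BIN_EDGES
) -> pd.DataFrame:
    """Replication rate per discovery P-value bin (eligible SNVs only).

    Bin b holds ``edges[b+1] < P <= edges[b]`` and the last bin holds
    ``P <= edges[-1]``: a boundary P belongs to the bin whose label starts
    with it, so P = 5e-9 exactly falls in "5e-9 to 5e-10" (bins written
    "5e-8 to > 5e-9" in the field's tables exclude their lower-significance
    edge).  Bins partition the eligible set.
    """
    merged = _merge_calls(snvs, calls)
    merged = merged[merged["significant_discovery"]]
    p = merged["p_discovery"].to_numpy()
    repl = merged["replicated"].to_numpy()
    masks = []
    for b in range(len(edges) - 1):
        masks.append(((p > edges[b + 1]) & (p <= edges[b]), P_BIN_LABELS[b]))
    masks.append((p <= edges[-1], P_BIN_LABELS[-1]))
    return _binned_rates(p, repl, masks)


def bin_by_or(
    snvs: pd.DataFrame, calls: pd.DataFrame, edges: tuple[float, ...] = OR_BIN_EDGES
) -> pd.DataFrame:
    """Replication rate per normalized discovery-OR bin (eligible SNVs only).

    Bins are lower-inclusive, upper-exclusive; the last bin is unbounded
    above.  Uses ``or_discovery_norm`` (all values >= 1 by construction).
    """
    merged = _merge_calls(snvs, calls)
    merged = merged[merged["significant_discovery"]]
    orr = merged["or_discovery_norm"].to_numpy()
    repl = merged["replicated"].to_numpy()
    masks = [
        ((orr >= edges[b]) & (orr < edges[b + 1]), OR_BIN_LABELS[b])
        for b in range(len(edges) - 1)
    ]
    return _binned_rates(orr, repl, masks)


def sensitivity_thresholds(
    snvs: pd.DataFrame,
    trait_label: str | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    lenient: float = DEFAULT_LENIENT_ALPHA,
) -> pd.DataFrame:
    """Threshold sensitivity analyses for one harmonized table.

    Three rows per trait: the primary rule (``alpha`` in both cohorts), the
    lenient rule (``lenient`` in both cohorts), and the Bonferroni rule
    (``alpha`` in discovery, 0.05/N in replication with N the trait's count
    of discovery-significant SNVs).  Raises ``ValueError`` if any trait has
    N = 0.
    """
    rows = []
    for trait, sub in snvs.groupby("trait_name", sort=False):
        label = trait_label or str(trait)
        primary = call_replication(sub, alpha, alpha)
        n_sig = int(primary["significant_discovery"].sum())
        if n_sig == 0:
            raise ValueError(f"no discovery-significant SNVs for {label!r}")
        bonf_alpha = 0.05 / n_sig
        for analysis, a_d, a_r in (
            ("primary", alpha, alpha),
            ("lenient", lenient, lenient),
            ("bonferroni", alpha, bonf_alpha),
        ):
            est = rate(call_replication(sub, a_d, a_r), label)
            row = est.as_dict()
            row.update({"analysis": analysis, "alpha_discovery": a_d, "alpha_replication": a_r})
            rows.append(row)
    cols = ["analysis", "stratum", "alpha_discovery", "alpha_replication",
            "k_replicated", "n_eligible", "rate", "ci_low", "ci_high", "ci_method"]
    return pd.DataFrame(rows)[cols]


def _merge_calls(snvs: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    return snvs.merge(
        calls[["variant_id", "trait_name", "significant_discovery", "replicated"]],
        on=["variant_id", "trait_name"],
        how="inner",
        validate="one_to_one",
    )
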