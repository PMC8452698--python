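"""Harmonization of a discovery/replication summary-statistics pair.

Three steps, run before any significance filtering so drop accounting covers
all shared SNVs:

1. **Intersect** — keep only rsIDs present in both cohorts.
2. **Align** — make the replication record report its effect for the
   discovery cohort's effect allele, negating the log-scale effect when the
   allele labels are exchanged; any other allele combination is dropped
   (``allele_mismatch``).  Strand flips and palindromic-SNP frequency checks
   are out of scope.
3. **Convert and normalize** — map every effect to the odds-ratio scale
   (binary log-odds are exponentiated; quantitative standardized betas go
   through the Chinn formula ``ln OR = beta * pi / sqrt(3)``), then map
   discovery ORs above 1, applying the same reciprocal to the replication OR
   so direction congruence is preserved.

Both the aligned (pre-normalization) and the normalized ORs are kept: the
replication call uses direction on the aligned scale, while binning, the
effect-change regression and the prediction model use the normalized scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TraitPair

#: slope of ln(OR) in a standardized mean difference (logistic/normal scaling)
CHINN_SLOPE = math.pi / math.sqrt(3.0)

HARMONIZED_COLUMNS = [
    "variant_id",
    "trait_name",
    "trait_type",
    "beta_discovery",
    "beta_replication",
    "or_discovery",
    "or_replication",
    "or_discovery_norm",
    "or_replication_norm",
    "normalized",
    "flipped",
    "p_discovery",
    "p_replication",
    "eaf_discovery",
    "maf_discovery",
    "info_replication",
    "sample_size_ratio",
]


@dataclass
class HarmonizeResult:
    """Harmonized SNV table plus intersection/alignment accounting."""

    table: pd.DataFrame
    n_discovery_only: int
    n_replication_only: int
    n_allele_mismatch: int


def intersect(pair: TraitPair) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inner-join the two cohort tables on rsID.

    Returns the merged frame (``_d`` / ``_r`` suffixes) and counts of ids
    private to either cohort.  Raises ``ValueError`` on empty intersection.
    """
    merged = pair.discovery.merge(
        pair.replication, on="variant_id", how="inner", suffixes=("_d", "_r")
    )
    counts = {
        "discovery_only": len(pair.discovery) - len(merged),
        "replication_only": len(pair.replication) - len(merged),
    }
    if merged.empty:
        raise ValueError(f"no shared rsIDs between cohorts for {pair.trait_name!r}")
    return merged, counts


def align_effect(
    d_effect_allele: str,
    d_other_allele: str,
    r_effect_allele: str,
    r_other_allele: str,
    r_effect: float,
) -> tuple[float, bool] | None:
    """Align one replication effect to the discovery allele labelling.

    Returns ``(aligned effect, flipped)`` or ``None`` when the allele pairs
    are incompatible (caller drops the SNV with reason ``allele_mismatch``).
    """
    if (r_effect_allele, r_other_allele) == (d_effect_allele, d_other_allele):
        return r_effect, False
    if (r_effect_allele, r_other_allele) == (d_other_allele, d_effect_allele):
        return -r_effect, True
    return None


def chinn_to_or(effect: float | np.ndarray) -> float | np.ndarray:
    """Standardized mean difference -> odds ratio: ``OR = exp(d * pi/sqrt 3)``."""
    return np.exp(np.asarray(effect, dtype=float) * CHINN_SLOPE)[()]


def or_to_chinn(odds_ratio: float | np.ndarray) -> float | np.ndarray:
    """Exact inverse of :func:`chinn_to_or`: ``d = ln(OR) * sqrt(3)/pi``."""
    return (np.log(np.asarray(odds_ratio, dtype=float)) / CHINN_SLOPE)[()]


def normalize_or(or_d, or_r):
    """Map discovery ORs above 1, reciprocating both cohorts' ORs together.

    The inversion is anchored on the discovery OR: if ``or_d < 1`` both ORs
    are reciprocated (preserving their relative direction); an OR of exactly
    1 is left untouched.  Idempotent.  Accepts scalars or arrays; returns
    ``(or_d_norm, or_r_transformed, normalized_flag)``.
    """
    or_d = np.asarray(or_d, dtype=float)
    or_r = np.asarray(or_r, dtype=float)
    if np.any(or_d <= 0) or np.any(or_r <= 0):
        raise ValueError("odds ratios must be positive")
    flag = or_d < 1.0
    out_d = np.where(flag, 1.0 / or_d, or_d)
    out_r = np.where(flag, 1.0 / or_r, or_r)
    return out_d[()], out_r[()], flag[()]


def harmonize_pair(pair: TraitPair, standardize_beta: bool = False) -> HarmonizeResult:
    """Run intersection, allele alignment, OR conversion and normalization.

    ``standardize_beta`` rescales quantitative effects by ``se * sqrt(n)``
    before the Chinn conversion, for input files whose betas are on a raw
    (unstandardized) outcome scale; it requires per-row ``n``.
    """
    merged, counts = intersect(pair)

    same = (merged["effect_allele_r"] == merged["effect_allele_d"]) & (
        merged["other_allele_r"] == merged["other_allele_d"]
    )
    swapped = (merged["effect_allele_r"] == merged["other_allele_d"]) & (
        merged["other_allele_r"] == merged["effect_allele_d"]
    )
    mismatch = ~(same | swapped)
    n_mismatch = int(mismatch.sum())
    merged = merged[~mismatch]
    if merged.empty:
        raise ValueError(f"all shared SNVs dropped as allele mismatches for {pair.trait_name!r}")

    flipped = swapped[~mismatch].to_numpy()
    beta_d = merged["effect_d"].to_numpy(dtype=float)
    beta_r = np.where(flipped, -merged["effect_r"].to_numpy(dtype=float), merged["effect_r"])

    if pair.trait_type == "quantitative":
        if standardize_beta:
            for col in ("se_d", "n_d", "se_r", "n_r"):
                if merged[col].isna().any():
                    raise ValueError("standardize_beta requires per-row se and n in both cohorts")
            # standardized effect ~ z / sqrt(n) = beta / (se * sqrt(n))
            beta_d = merged["effect_d"].to_numpy() / (
                merged["se_d"].to_numpy() * np.sqrt(merged["n_d"].to_numpy())
            )
            beta_r = np.where(flipped, -1.0, 1.0) * merged["effect_r"].to_numpy() / (
                merged["se_r"].to_numpy() * np.sqrt(merged["n_r"].to_numpy())
            )
        or_d = chinn_to_or(beta_d)
        or_r = chinn_to_or(beta_r)
    else:
        or_d = np.exp(beta_d)
        or_r = np.exp(beta_r)

    or_d_norm, or_r_norm, normalized = normalize_or(or_d, or_r)

    eaf_d = merged["eaf_d"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "variant_id": merged["variant_id"].to_numpy(),
            "trait_name": pair.trait_name,
            "trait_type": pair.trait_type,
            "beta_discovery": beta_d,
            "beta_replication": beta_r,
            "or_discovery": or_d,
            "or_replication": or_r,
            "or_discovery_norm": or_d_norm,
            "or_replication_norm": or_r_norm,
            "normalized": normalized,
            "flipped": flipped,
            "p_discovery": merged["p_value_d"].to_numpy(dtype=float),
            "p_replication": merged["p_value_r"].to_numpy(dtype=float),
            "eaf_discovery": eaf_d,
            "maf_discovery": np.minimum(eaf_d, 1.0 - eaf_d),
            "info_replication": merged["info_r"].to_numpy(dtype=float),
            "sample_size_ratio": pair.n_replication / pair.n_discovery,
        }
    ).reset_index(drop=True)

    return HarmonizeResult(
        table=table,
        n_discovery_only=counts["discovery_only"],
        n_replication_only=counts["replication_only"],
        n_allele_mismatch=n_mismatch,
    )
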