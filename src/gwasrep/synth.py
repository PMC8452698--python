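"""Synthetic paired discovery/replication GWAS with known ground truth.

The generator emulates the statistical structure of two independent cohorts
measuring the same per-variant true effects:

* true standardized effects follow a point-normal distribution — zero with
  probability ``frac_null``, else Normal(0, tau^2);
* per-cohort sampling noise has the standard large-sample standard error,
  ``1/sqrt(2 n f (1-f))`` for a standardized quantitative effect at allele
  frequency ``f``, and ``sqrt(1/(2 n phi (1-phi) f (1-f)))`` for a log-odds
  effect with case fraction ``phi`` (the usual logistic score approximation;
  only the scaling with n, f and phi is relied upon);
* the replication file may carry effect/other-allele swaps (with the effect
  negated), so harmonization has real work to undo, and may be missing a
  fraction of rsIDs;
* imputation INFO scores are Beta-distributed in the replication table.

One master seed drives everything; each randomization stage draws from its
own child stream (via :class:`numpy.random.SeedSequence` spawning), so
toggling one stage never perturbs the draws of another.  Linkage
disequilibrium between variants is deliberately not modelled: every SNV is
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import TraitPair

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated discovery/replication pair."""

    n_snvs: int = 10_000
    frac_null: float = 0.9
    tau: float = 0.05                     # SD of true standardized effects under the alternative
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_discovery: int = 20_000
    n_replication: int = 100_000
    trait_type: str = "quantitative"
    case_fraction: float = 0.5            # binary traits only
    p_allele_swap: float = 0.0
    p_missing_rsid: float = 0.0
    info_params: tuple[float, float] = (20.0, 2.0)
    seed: int = 0
    trait_name: str = "synthetic_trait"

    def __post_init__(self) -> None:
        if self.n_snvs <= 0:
            raise ValueError("n_snvs must be positive")
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValueError("frac_null must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5] with lo <= hi")
        if self.n_discovery <= 0 or self.n_replication <= 0:
            raise ValueError("cohort sample sizes must be positive")
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        for p in (self.p_allele_swap, self.p_missing_rsid):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.info_params) <= 0:
            raise ValueError("info_params must be positive Beta shapes")


def effect_se(maf: np.ndarray, n: int, trait_type: str, case_fraction: float = 0.5) -> np.ndarray:
    """Large-sample standard error of a per-allele effect estimate."""
    het = 2.0 * maf * (1.0 - maf)
    if trait_type == "quantitative":
        return 1.0 / np.sqrt(n * het)
    phi = case_fraction
    return np.sqrt(1.0 / (n * phi * (1.0 - phi) * het))


def simulate_pair(config: SimConfig) -> tuple[TraitPair, pd.DataFrame]:
    """Simulate one discovery/replication pair plus its ground truth.

    Returns the :class:`~gwasrep.io.TraitPair` and a ground-truth DataFrame
    with, per SNV: the true standardized effect, true MAF, null indicator,
    per-cohort standard errors, and the swap / missing-rsID masks actually
    applied.  Byte-identical output is guaranteed for identical configs.
    """
    cfg = config
    # independent child streams per randomization stage: adding or toggling a
    # stage never perturbs the draws of earlier stages
    children = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_truth, rng_disc, rng_rep, rng_swap, rng_miss, rng_info = (
        np.random.default_rng(s) for s in children
    )

    n = cfg.n_snvs
    lo, hi = cfg.maf_range
    maf = rng_truth.uniform(lo, hi, size=n)
    is_null = rng_truth.random(n) < cfg.frac_null
    beta_true = np.where(is_null, 0.0, rng_truth.normal(0.0, cfg.tau, size=n))

    pair_idx = rng_truth.integers(0, len(_ALLELE_PAIRS), size=n)
    effect_allele = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    other_allele = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    se_d = effect_se(maf, cfg.n_discovery, cfg.trait_type, cfg.case_fraction)
    se_r = effect_se(maf, cfg.n_replication, cfg.trait_type, cfg.case_fraction)
    beta_d = beta_true + rng_disc.normal(0.0, se_d)
    beta_r = beta_true + rng_rep.normal(0.0, se_r)
    p_d = 2.0 * stats.norm.sf(np.abs(beta_d / se_d))
    p_r = 2.0 * stats.norm.sf(np.abs(beta_r / se_r))
    # two-sided Wald P; clip the P = 0 underflow to the smallest positive float
    tiny = np.finfo(float).tiny
    p_d = np.clip(p_d, tiny, 1.0)
    p_r = np.clip(p_r, tiny, 1.0)

    variant_id = np.array([f"rs{i + 1}" for i in range(n)])

    discovery = pd.DataFrame(
        {
            "variant_id": variant_id,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "effect": beta_d,
            "se": se_d,
            "p_value": p_d,
            "eaf": maf,
            "info": np.nan,
            "n": float(cfg.n_discovery),
        }
    )

    swapped = rng_swap.random(n) < cfg.p_allele_swap
    missing = rng_miss.random(n) < cfg.p_missing_rsid
    info = rng_info.beta(cfg.info_params[0], cfg.info_params[1], size=n)

    replication = pd.DataFrame(
        {
            "variant_id": variant_id,
            "effect_allele": np.where(swapped, other_allele, effect_allele),
            "other_allele": np.where(swapped, effect_allele, other_allele),
            "effect": np.where(swapped, -beta_r, beta_r),
            "se": se_r,
            "p_value": p_r,
            "eaf": np.where(swapped, 1.0 - maf, maf),
            "info": info,
            "n": float(cfg.n_replication),
        }
    )
    replication = replication[~missing].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "variant_id": variant_id,
            "beta_true": beta_true,
            "maf": maf,
            "is_null": is_null,
            "se_discovery": se_d,
            "se_replication": se_r,
            "swapped": swapped,
            "missing_in_replication": missing,
        }
    )

    pair = TraitPair(
        trait_name=cfg.trait_name,
        trait_type=cfg.trait_type,
        discovery=discovery,
        replication=replication,
        n_discovery=cfg.n_discovery,
        n_replication=cfg.n_replication,
    )
    return pair, truth


def expected_shrinkage(
    effect: float, se: float, threshold_z: float, absolute: bool = False
) -> float:
    """Conditional mean of an observed effect given two-sided selection.

    For an estimate ``X ~ Normal(effect, se^2)`` selected because
    ``|X / se| > threshold_z``, returns ``E[X | selected]`` (or
    ``E[|X| | selected]`` with ``absolute=True``) via the truncated-normal
    closed form.  This is the analytic winner's-curse oracle: the expectation
    exceeds the true effect in magnitude whenever selection is not certain.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if threshold_z <= 0:
        raise ValueError("threshold_z must be positive")
    mu, c = float(effect), float(threshold_z)
    a = c - mu / se        # (c*se - mu)/se, upper tail boundary in Z units
    b = -c - mu / se       # lower tail boundary
    p_sel = stats.norm.sf(a) + stats.norm.cdf(b)
    if p_sel <= 0:
        raise FloatingPointError("selection probability underflowed to zero")
    if not absolute:
        # E[Z | Z>a or Z<b] = (phi(a) - phi(b)) / p_sel
        return mu + se * (stats.norm.pdf(a) - stats.norm.pdf(b)) / p_sel
    upper = mu * stats.norm.sf(a) + se * stats.norm.pdf(a)     # E[X; X > c*se]
    lower = mu * stats.norm.cdf(b) - se * stats.norm.pdf(b)    # E[X; X < -c*se]
    return (upper - lower) / p_sel


def study_scenario(seed: int) -> list[SimConfig]:
    """The package's default synthetic multi-trait study.

    Four traits — two binary, two quantitative — chosen to mirror the shape
    of a real discovery-vs-biobank comparison: discovery cohorts of 20-30k,
    replication cohorts equal to or several-fold larger, point-normal true
    effects with ~10% non-null SNVs, and distinct replication/discovery
    sample-size ratios per trait (so the ratio is not collinear with trait
    type in the prediction model).  Binary traits get somewhat larger true
    effects (tau 0.08 log-odds vs 0.05 standardized), as binary GWAS of
    comparable power typically report larger per-allele effects.  Per-trait
    seeds are derived deterministically from ``seed``.

    The resulting eligible set is ~5-6k SNVs per run, with moderate
    replication for the binary traits and high replication for the
    quantitative ones — the regime in which discovery OR, P-value category
    and trait type all carry signal about replication.
    """
    base = [
        dict(trait_name="binary_trait_a", trait_type="binary", n_snvs=60_000, tau=0.08,
             n_discovery=20_000, n_replication=20_000),
        dict(trait_name="binary_trait_b", trait_type="binary", n_snvs=60_000, tau=0.08,
             n_discovery=25_000, n_replication=40_000),
        dict(trait_name="quant_trait_a", trait_type="quantitative", n_snvs=80_000, tau=0.05,
             n_discovery=20_000, n_replication=60_000),
        dict(trait_name="quant_trait_b", trait_type="quantitative", n_snvs=70_000, tau=0.05,
             n_discovery=30_000, n_replication=45_000),
    ]
    children = np.random.SeedSequence(seed).spawn(len(base))
    return [
        SimConfig(
            frac_null=0.9,
            p_allele_swap=0.2,
            p_missing_rsid=0.02,
            seed=int(child.generate_state(1)[0] % (2**31)),
            **kwargs,
        )
        for kwargs, child in zip(base, children)
    ]


def write_simulation(pair: TraitPair, truth: pd.DataFrame, outdir: str) -> dict[str, str]:
    """Write a simulated pair as sumstats files + manifest + ground truth."""
    import os

    from . import io as _io

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "discovery": os.path.join(outdir, "discovery.tsv"),
        "replication": os.path.join(outdir, "replication.tsv"),
        "truth": os.path.join(outdir, "ground_truth.tsv"),
        "manifest": os.path.join(outdir, "manifest.yaml"),
    }
    _io.write_sumstats(pair.discovery, paths["discovery"])
    _io.write_sumstats(pair.replication, paths["replication"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.15g")
    with open(paths["manifest"], "w") as fh:
        fh.write(
            "traits:\n"
            f"  - name: {pair.trait_name}\n"
            f"    type: {pair.trait_type}\n"
            "    discovery: discovery.tsv\n"
            "    replication: replication.tsv\n"
            f"    n_discovery: {pair.n_discovery}\n"
            f"    n_replication: {pair.n_replication}\n"
        )
    return paths
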