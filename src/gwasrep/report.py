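"""Pipeline orchestration: one config in, the full table bundle out.

:func:`run_all` composes the stages in their natural order —
simulate-or-read, harmonize, classify replication, per-trait and pooled
rates, P-value/OR bins, threshold sensitivity analyses, the effect-change
regression, and the replication prediction model — and returns (optionally
writing) the output bundle.  Three input sources are supported:

* ``manifest`` — a YAML manifest of real summary-statistics file pairs;
* ``simulate`` — a list of :class:`~gwasrep.synth.SimConfig`-style mappings
  (per-trait seeds are derived deterministically from the master seed);
* ``counts`` — pre-called per-trait counts (k replicated out of n
  significant), which drive only the rate and pooling stages.  This is how
  published count tables are re-analysed without raw SNV data.

Runs are deterministic given the config including its master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import effect_change as ec
from . import harmonize as hz
from . import io as gio
from . import meta
from . import predict as pr
from . import replicate as rp
from . import synth


@dataclass
class RunConfig:
    """Everything one pipeline run needs; every stage option has a default."""

    manifest: str | None = None
    simulate: Sequence[Mapping[str, Any]] | None = None
    counts: pd.DataFrame | Sequence[Mapping[str, Any]] | None = None
    alpha_discovery: float = rp.GENOME_WIDE_ALPHA
    alpha_replication: float = rp.GENOME_WIDE_ALPHA
    lenient_alpha: float = rp.DEFAULT_LENIENT_ALPHA
    pooling_method: str = "pooled_counts"  # or "iv_fixed"
    iv_scale: str = "proportion"
    effect_change_intercept: bool = True
    prediction: bool = True
    threshold_rule: str = "youden"
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.manifest, self.simulate, self.counts)]
        if sum(sources) != 1:
            raise ValueError("config needs exactly one input source: manifest, simulate or counts")


def load_run_config(path: str) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def _rates_frame(estimates: list[rp.RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.as_dict() for e in estimates])


def _pool(config: RunConfig, estimates: list[rp.RateEstimate], label: str) -> meta.PooledRate:
    # strata with < 2 member traits fall back to pooled counts
    if config.pooling_method == "iv_fixed" and len(estimates) >= 2:
        return meta.iv_fixed(estimates, scale=config.iv_scale, label=label)
    return meta.pool_counts(estimates, label=label)


def _pooled_frame(
    config: RunConfig, per_trait: list[rp.RateEstimate], trait_types: Mapping[str, str]
) -> pd.DataFrame:
    groups = {"all": per_trait}
    for ttype in ("binary", "quantitative"):
        members = [e for e in per_trait if trait_types.get(e.stratum_label) == ttype]
        if members:
            groups[ttype] = members
    return pd.DataFrame([_pool(config, ests, label).as_dict() for label, ests in groups.items()])


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage the input source supports; return the output bundle.

    Any stage failure is re-raised with the stage name attached.  When
    ``config.outdir`` is set the bundle is also written there via
    :func:`gwasrep.io.write_report`.
    """
    if config.counts is not None:
        bundle = _run_from_counts(config)
    else:
        bundle = _run_from_snvs(config)
    if config.outdir is not None:
        gio.write_report(bundle, config.outdir)
    return bundle


def _run_from_counts(config: RunConfig) -> dict[str, Any]:
    counts = config.counts
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(list(counts))
    estimates = [
        rp.rate_from_counts(int(r.k_replicated), int(r.n_significant), str(r.trait_name))
        for r in counts.itertuples()
    ]
    trait_types = dict(zip(counts["trait_name"], counts["trait_type"]))
    return {
        "per_trait_rates": _rates_frame(estimates),
        "pooled_rates": _pooled_frame(config, estimates, trait_types),
        "summary": {
            "input_source": "pre-called counts",
            "n_traits": len(estimates),
            "n_significant_total": int(sum(e.n for e in estimates)),
            "n_replicated_total": int(sum(e.k for e in estimates)),
            "pooling_method": config.pooling_method,
        },
    }


def _load_pairs(config: RunConfig) -> list[gio.TraitPair]:
    if config.manifest is not None:
        return [gio.load_trait_pair(spec) for spec in gio.read_manifest(config.manifest)]
    # deterministic per-trait child seeds from the master seed
    children = np.random.SeedSequence(config.seed).spawn(len(config.simulate))
    pairs = []
    for entry, child in zip(config.simulate, children):
        kwargs = dict(entry)
        kwargs.setdefault("seed", int(child.generate_state(1)[0] % (2**31)))
        pairs.append(synth.simulate_pair(synth.SimConfig(**kwargs))[0])
    return pairs


def _run_from_snvs(config: RunConfig) -> dict[str, Any]:
    stage = "input"
    try:
        pairs = _load_pairs(config)

        stage = "harmonize"
        tables, drop_rows = [], []
        for pair in pairs:
            res = hz.harmonize_pair(pair)
            tables.append(res.table)
            drop_rows.append(
                {
                    "trait_name": pair.trait_name,
                    "discovery_only": res.n_discovery_only,
                    "replication_only": res.n_replication_only,
                    "allele_mismatch": res.n_allele_mismatch,
                }
            )
        snvs = pd.concat(tables, ignore_index=True)

        stage = "replicate"
        calls = rp.call_replication(snvs, config.alpha_discovery, config.alpha_replication)
        estimates = [
            rp.rate(calls[calls["trait_name"] == p.trait_name], p.trait_name) for p in pairs
        ]
        trait_types = {p.trait_name: p.trait_type for p in pairs}
        p_bins = rp.bin_by_p(snvs, calls)
        or_bins = rp.bin_by_or(snvs, calls)
        sensitivity = rp.sensitivity_thresholds(
            snvs, alpha=config.alpha_discovery, lenient=config.lenient_alpha
        )

        stage = "meta"
        pooled = _pooled_frame(config, estimates, trait_types)

        stage = "effect_change"
        change = ec.effect_change_table(snvs, calls, with_intercept=config.effect_change_intercept)

        bundle: dict[str, Any] = {
            "harmonized": snvs,
            "calls": calls,
            "per_trait_rates": _rates_frame(estimates),
            "pooled_rates": pooled,
            "p_bin_rates": p_bins,
            "or_bin_rates": or_bins,
            "sensitivity_rates": sensitivity,
            "effect_change": change,
        }

        summary: dict[str, Any] = {
            "input_source": "manifest" if config.manifest else "simulation",
            "seed": config.seed,
            "n_traits": len(pairs),
            "n_shared_snvs": len(snvs),
            "n_significant_total": int(calls["significant_discovery"].sum()),
            "n_replicated_total": int(calls["replicated"].sum()),
            "alpha_discovery": config.alpha_discovery,
            "alpha_replication": config.alpha_replication,
        }
        for row in drop_rows:
            summary[f"drops[{row['trait_name']}]"] = (
                f"discovery_only={row['discovery_only']} "
                f"replication_only={row['replication_only']} "
                f"allele_mismatch={row['allele_mismatch']}"
            )

        if config.prediction:
            stage = "predict"
            try:
                dataset = pr.make_dataset(snvs, calls)
            except ValueError as exc:
                summary["prediction_skipped"] = str(exc)
            else:
                split_seed = int(
                    np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0] % (2**31)
                )
                train, test = pr.split_train_test(dataset, split_seed)
                fit = pr.fit_logistic(train)
                metrics, roc = pr.evaluate(fit, test, config.threshold_rule)
                bundle["prediction_metrics"] = metrics.as_frame()
                bundle["prediction_coefficients"] = fit.coefficients
                bundle["roc_coordinates"] = roc
                summary["prediction_rows"] = len(dataset)
                summary["prediction_split_seed"] = split_seed

        bundle["summary"] = summary
        return bundle
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def plot_rates(rates: pd.DataFrame, path: str) -> None:
    """Simple per-stratum replication-rate bar chart with 95% CI bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4.0, 0.9 * len(rates)), 4.0))
    x = np.arange(len(rates))
    r = rates["rate"].to_numpy(dtype=float)
    err = np.vstack([r - rates["ci_low"], rates["ci_high"] - r])
    ax.bar(x, r, color="#4878a8")
    ax.errorbar(x, r, yerr=np.clip(err, 0, None), fmt="none", ecolor="black", capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(rates["stratum"], rotation=45, ha="right")
    ax.set_ylabel("replication rate")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
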