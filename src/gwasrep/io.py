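"""Reading, validating and writing GWAS summary-statistics tables.

Summary-statistics files are tab-delimited UTF-8 text with a single header
line.  Column names vary wildly between GWAS consortia, so every reader
accepts a :class:`ColumnSchema` mapping; the defaults follow the common
``SNP / A1 / A2 / BETA (or OR) / SE / P / EAF / INFO / N`` convention.

Effects supplied as odds ratios are converted to the log scale on read so a
single internal effect scale exists per table; the conversion is recorded on
the returned :class:`SumstatsRead`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

VALID_ALLELES = frozenset("ACGT")

#: canonical internal column names, in output order
CORE_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "effect",
    "se",
    "p_value",
    "eaf",
    "info",
    "n",
]


class SchemaError(ValueError):
    """A mandatory column is absent or the manifest is malformed."""


@dataclass(frozen=True)
class ColumnSchema:
    """Mapping from a file's column names to the internal schema.

    ``effect`` is used when the file reports a (log-scale or standardized)
    beta; ``odds_ratio`` when it reports an odds ratio instead.  If both are
    present the beta column wins.
    """

    variant_id: str = "SNP"
    effect_allele: str = "A1"
    other_allele: str = "A2"
    effect: str = "BETA"
    odds_ratio: str = "OR"
    se: str = "SE"
    p_value: str = "P"
    eaf: str = "EAF"
    info: str = "INFO"
    n: str = "N"


@dataclass
class SumstatsRead:
    """Validated summary statistics plus row-level drop accounting."""

    table: pd.DataFrame
    drops: dict[str, int]
    n_input: int
    converted_from_or: bool = False

    @property
    def n_kept(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class TraitSpec:
    """One manifest entry: a named discovery/replication file pair."""

    trait_name: str
    trait_type: str  # "binary" | "quantitative"
    discovery_path: str
    replication_path: str
    n_discovery: int
    n_replication: int


@dataclass
class TraitPair:
    """A discovery/replication cohort pair with trait metadata.

    ``trait_type`` determines the effect scale of both member tables:
    log-odds for binary traits, standardized beta for quantitative traits.
    """

    trait_name: str
    trait_type: str
    discovery: pd.DataFrame
    replication: pd.DataFrame
    n_discovery: int
    n_replication: int

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.n_discovery <= 0 or self.n_replication <= 0:
            raise ValueError("cohort sample sizes must be positive")


def read_sumstats(path: str, schema: ColumnSchema | Mapping[str, str] | None = None) -> SumstatsRead:
    """Read and validate one summary-statistics table.

    Rows failing validation are dropped and counted by reason; duplicate
    variant ids are resolved by keeping the smallest P value (remainder
    counted under ``duplicate_id``).

    Raises
    ------
    SchemaError
        If a mandatory column is missing (the error names the column).
    ValueError
        If no valid rows remain after validation.
    """
    if schema is None:
        schema = ColumnSchema()
    elif isinstance(schema, Mapping):
        schema = replace(ColumnSchema(), **dict(schema))

    raw = pd.read_csv(path, sep="\t", dtype={schema.variant_id: str})
    n_input = len(raw)

    mandatory = {
        "variant_id": schema.variant_id,
        "effect_allele": schema.effect_allele,
        "other_allele": schema.other_allele,
        "se": schema.se,
        "p_value": schema.p_value,
    }
    for internal, col in mandatory.items():
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column {col!r} (maps to {internal!r})")

    converted_from_or = False
    if schema.effect in raw.columns:
        effect = pd.to_numeric(raw[schema.effect], errors="coerce")
    elif schema.odds_ratio in raw.columns:
        orr = pd.to_numeric(raw[schema.odds_ratio], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            effect = pd.Series(np.where(orr > 0, np.log(orr), np.nan), index=raw.index)
        converted_from_or = True
    else:
        raise SchemaError(
            f"missing mandatory column {schema.effect!r} or {schema.odds_ratio!r} (maps to 'effect')"
        )

    df = pd.DataFrame(
        {
            "variant_id": raw[schema.variant_id].astype(str).str.strip(),
            "effect_allele": raw[schema.effect_allele].astype(str).str.strip().str.upper(),
            "other_allele": raw[schema.other_allele].astype(str).str.strip().str.upper(),
            "effect": effect,
            "se": pd.to_numeric(raw[schema.se], errors="coerce"),
            "p_value": pd.to_numeric(raw[schema.p_value], errors="coerce"),
        }
    )
    for opt in ("eaf", "info", "n"):
        col = getattr(schema, opt)
        df[opt] = pd.to_numeric(raw[col], errors="coerce") if col in raw.columns else np.nan

    drops: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            drops[reason] = drops.get(reason, 0) + k
            df = df[~mask]

    _drop(df["variant_id"].eq("") | df["variant_id"].isna(), "empty_variant_id")
    _drop(df["effect"].isna() | df["se"].isna() | df["p_value"].isna(), "missing_core_field")
    _drop(~df["effect_allele"].isin(VALID_ALLELES), "bad_allele")
    _drop(~df["other_allele"].isin(VALID_ALLELES), "bad_allele")
    _drop(df["effect_allele"] == df["other_allele"], "same_alleles")
    _drop(df["se"] <= 0, "nonpositive_se")
    _drop(df["p_value"] <= 0, "nonpositive_p")
    _drop(df["p_value"] > 1, "p_above_one")

    # optional fields outside their domain are demoted to missing, not dropped
    df.loc[~df["eaf"].between(0, 1, inclusive="neither"), "eaf"] = np.nan
    df.loc[~df["info"].between(0, 1, inclusive="both"), "info"] = np.nan
    df.loc[~(df["n"] > 0), "n"] = np.nan

    # duplicate rsIDs: keep the smallest P value (deterministic tie-break)
    if df["variant_id"].duplicated().any():
        before = len(df)
        df = df.sort_values(["p_value", "variant_id"], kind="mergesort")
        df = df[~df["variant_id"].duplicated(keep="first")]
        drops["duplicate_id"] = before - len(df)

    df = df.sort_index().reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no valid rows remain after validation of {path}")

    assert n_input == len(df) + sum(drops.values())
    return SumstatsRead(table=df, drops=drops, n_input=n_input, converted_from_or=converted_from_or)


def write_sumstats(table: pd.DataFrame, path: str, schema: ColumnSchema | None = None) -> None:
    """Write a validated table back to tab-delimited text.

    Floats are written with 15 significant digits so a write/read round trip
    preserves every field well beyond 12 significant digits.
    """
    schema = schema or ColumnSchema()
    out = table.copy()
    rename = {
        "variant_id": schema.variant_id,
        "effect_allele": schema.effect_allele,
        "other_allele": schema.other_allele,
        "effect": schema.effect,
        "se": schema.se,
        "p_value": schema.p_value,
        "eaf": schema.eaf,
        "info": schema.info,
        "n": schema.n,
    }
    out = out[[c for c in CORE_COLUMNS if c in out.columns]].rename(columns=rename)
    out.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_manifest(path: str) -> list[TraitSpec]:
    """Read the trait manifest (YAML).

    Expected layout::

        traits:
          - name: Asthma
            type: binary
            discovery: asthma_discovery.tsv
            replication: asthma_replication.tsv
            n_discovery: 100000
            n_replication: 125309

    Relative file paths are resolved against the manifest's directory.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = (doc or {}).get("traits") or []
    if not entries:
        raise SchemaError(f"manifest {path} lists no traits")
    base = os.path.dirname(os.path.abspath(path))

    specs: list[TraitSpec] = []
    seen: set[str] = set()
    for i, entry in enumerate(entries):
        name = str(entry.get("name", "")).strip()
        ttype = str(entry.get("type", "")).strip().lower()
        if not name:
            raise SchemaError(f"manifest entry {i + 1} has no trait name")
        if name in seen:
            raise SchemaError(f"duplicate trait name in manifest: {name!r}")
        seen.add(name)
        if ttype not in ("binary", "quantitative"):
            raise SchemaError(f"manifest entry {name!r}: unknown trait_type {ttype!r}")
        try:
            n_d = int(entry["n_discovery"])
            n_r = int(entry["n_replication"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"manifest entry {name!r}: bad or missing sample sizes") from exc
        if n_d <= 0 or n_r <= 0:
            raise SchemaError(f"manifest entry {name!r}: sample sizes must be positive")
        specs.append(
            TraitSpec(
                trait_name=name,
                trait_type=ttype,
                discovery_path=os.path.join(base, str(entry["discovery"])),
                replication_path=os.path.join(base, str(entry["replication"])),
                n_discovery=n_d,
                n_replication=n_r,
            )
        )
    return specs


def load_trait_pair(spec: TraitSpec, schema: ColumnSchema | None = None) -> TraitPair:
    """Read both member tables of one manifest entry."""
    disc = read_sumstats(spec.discovery_path, schema)
    repl = read_sumstats(spec.replication_path, schema)
    return TraitPair(
        trait_name=spec.trait_name,
        trait_type=spec.trait_type,
        discovery=disc.table,
        replication=repl.table,
        n_discovery=spec.n_discovery,
        n_replication=spec.n_replication,
    )


# ---------------------------------------------------------------------------
# pipeline output bundle
# ---------------------------------------------------------------------------

#: bundle key -> output file name; DataFrames become tab-delimited tables
_TABLE_FILES = {
    "per_trait_rates": "per_trait_rates.tsv",
    "pooled_rates": "pooled_rates.tsv",
    "p_bin_rates": "p_bin_rates.tsv",
    "or_bin_rates": "or_bin_rates.tsv",
    "sensitivity_rates": "sensitivity_rates.tsv",
    "effect_change": "effect_change.tsv",
    "prediction_metrics": "prediction_metrics.tsv",
    "prediction_coefficients": "prediction_coefficients.tsv",
    "roc_coordinates": "roc_coordinates.tsv",
    "calls": "replication_calls.tsv",
    "harmonized": "harmonized_snvs.tsv",
}


def write_report(results: Mapping[str, object], path: str) -> list[str]:
    """Write a pipeline output bundle to ``path``.

    ``results`` maps bundle keys (see ``_TABLE_FILES``) to DataFrames, plus an
    optional ``"summary"`` mapping written as ``key: value`` lines.  Sections
    absent from the bundle are simply not written.  Floats are printed with 10
    significant digits so re-reading reproduces values at printed precision.
    Returns the list of files written.
    """
    os.makedirs(path, exist_ok=True)
    written: list[str] = []
    for key, fname in _TABLE_FILES.items():
        if key not in results or results[key] is None:
            continue
        df = results[key]
        if not isinstance(df, pd.DataFrame):
            raise TypeError(f"bundle entry {key!r} must be a DataFrame")
        target = os.path.join(path, fname)
        df.to_csv(target, sep="\t", index=False, float_format="%.10g")
        written.append(target)
    summary = results.get("summary")
    if summary is not None:
        target = os.path.join(path, "run_summary.txt")
        with open(target, "w") as fh:
            for k, v in dict(summary).items():
                fh.write(f"{k}: {v}\n")
        written.append(target)
    return written
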