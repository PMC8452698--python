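"""Logistic prediction of per-SNV replication.

The model predicts, for each discovery-significant SNV, whether it will
replicate, from: the normalized discovery OR (numeric), the discovery
P-value category (four levels, reference "5e-8 to 5e-9"), a continuous
P-value term entered as -log10(P) (raw P spans ~40 orders of magnitude and
underflows), the trait type (binary vs quantitative), the discovery minor
allele frequency, the replication imputation INFO score, and the
replication/discovery sample-size ratio.

The data are split randomly in half into train and test sets; the model is
a maximum-likelihood logistic regression fitted on the train half and
evaluated on the test half: AUC with a DeLong 95% CI,
sensitivity/specificity at a configurable score threshold (Youden-optimal
on the test ROC by default, fixed 0.5 as the alternative) with Wilson CIs,
and McFadden's pseudo-R^2 from the training fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from scipy import stats
from sklearn.metrics import roc_curve

from .replicate import P_BIN_EDGES, P_BIN_LABELS, wilson_ci

P_CATEGORY_REFERENCE = P_BIN_LABELS[0]  # "5e-8 to 5e-9"

DEFAULT_FORMULA = (
    "replicated ~ or_discovery"
    ' + C(p_category, Treatment(reference="5e-8 to 5e-9"))'
    " + neglog10_p"
    " + C(trait_type)"
    " + maf + info + sample_size_ratio"
)

#: columns a model row must have non-missing
_MODEL_COLUMNS = [
    "replicated",
    "or_discovery",
    "p_category",
    "neglog10_p",
    "trait_type",
    "maf",
    "info",
    "sample_size_ratio",
]


def p_value_category(p: np.ndarray, edges=P_BIN_EDGES, labels=P_BIN_LABELS) -> np.ndarray:
    """Discovery P-value bin label per SNV (same boundaries as bin_by_p:
    a boundary P belongs to the bin whose label starts with it)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, "", dtype=object)
    for b in range(len(edges) - 1):
        out[(p > edges[b + 1]) & (p <= edges[b])] = labels[b]
    out[p <= edges[-1]] = labels[-1]
    return out


@dataclass
class PredictionDataset:
    """Model-ready rows (one per discovery-significant SNV) + drop counts."""

    frame: pd.DataFrame
    n_input: int
    drops: dict[str, int]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LogisticFit:
    """A fitted replication model with its coefficient table."""

    coefficients: pd.DataFrame  # term, estimate, se, z, p_value, ci_low, ci_high
    llf: float
    llnull: float
    mcfadden_r2: float
    converged: bool
    separation_flag: bool
    penalized: bool
    formula: str
    n_train: int
    _result: object = field(repr=False, default=None)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted replication probability per row."""
        return np.asarray(self._result.predict(data), dtype=float)


@dataclass(frozen=True)
class ModelMetrics:
    """Discrimination and fit metrics of the replication model."""

    auc: float
    auc_ci_low: float
    auc_ci_high: float
    sensitivity: float
    sens_ci_low: float
    sens_ci_high: float
    specificity: float
    spec_ci_low: float
    spec_ci_high: float
    mcfadden_r2: float
    threshold: float
    threshold_rule: str
    n_test: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("auc", self.auc, self.auc_ci_low, self.auc_ci_high),
            ("sensitivity", self.sensitivity, self.sens_ci_low, self.sens_ci_high),
            ("specificity", self.specificity, self.spec_ci_low, self.spec_ci_high),
            ("mcfadden_r2", self.mcfadden_r2, np.nan, np.nan),
            ("threshold", self.threshold, np.nan, np.nan),
        ]
        df = pd.DataFrame(rows, columns=["metric", "value", "ci_low", "ci_high"])
        df["threshold_rule"] = self.threshold_rule
        df["n_test"] = self.n_test
        return df


def make_dataset(snvs: pd.DataFrame, calls: pd.DataFrame, min_rows: int = 50) -> PredictionDataset:
    """Assemble the per-SNV model table from harmonized SNVs and calls.

    Keeps discovery-significant SNVs only; rows missing MAF or INFO are
    dropped and counted.  Raises ``ValueError`` below ``min_rows`` complete
    rows (the model is not fit at smaller n).
    """
    df = snvs.merge(
        calls[["variant_id", "trait_name", "significant_discovery", "replicated"]],
        on=["variant_id", "trait_name"],
        how="inner",
        validate="one_to_one",
    )
    df = df[df["significant_discovery"]]
    n_input = len(df)

    frame = pd.DataFrame(
        {
            "variant_id": df["variant_id"].to_numpy(),
            "trait_name": df["trait_name"].to_numpy(),
            "replicated": df["replicated"].to_numpy().astype(int),
            "or_discovery": df["or_discovery_norm"].to_numpy(dtype=float),
            "p_category": p_value_category(df["p_discovery"].to_numpy()),
            "neglog10_p": -np.log10(df["p_discovery"].to_numpy(dtype=float)),
            "trait_type": df["trait_type"].to_numpy(),
            "maf": df["maf_discovery"].to_numpy(dtype=float),
            "info": df["info_replication"].to_numpy(dtype=float),
            "sample_size_ratio": df["sample_size_ratio"].to_numpy(dtype=float),
        }
    )
    drops: dict[str, int] = {}
    for col in ("maf", "info"):
        miss = frame[col].isna()
        if miss.any():
            drops[f"missing_{col}"] = int(miss.sum())
            frame = frame[~miss]
    frame = frame.reset_index(drop=True)
    if len(frame) < min_rows:
        raise ValueError(
            f"only {len(frame)} complete rows (< {min_rows}); model not fit at this size"
        )
    return PredictionDataset(frame=frame, n_input=n_input, drops=drops)


def split_train_test(dataset: PredictionDataset | pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random half/half split, reproducible from ``seed``; sizes differ by <= 1."""
    frame = dataset.frame if isinstance(dataset, PredictionDataset) else dataset
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(frame))
    half = len(frame) // 2
    train = frame.iloc[np.sort(idx[:half])].reset_index(drop=True)
    test = frame.iloc[np.sort(idx[half:])].reset_index(drop=True)
    return train, test


def fit_logistic(
    train: pd.DataFrame,
    formula: str | None = None,
    penalize_on_separation: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression on the train half.

    Predictors whose category has a single level in the train data (e.g. one
    trait type only) are dropped from the formula automatically.  Perfect or
    quasi-perfect separation is flagged; when ``penalize_on_separation`` is
    true an L2-penalized refit (no standard errors) replaces the diverged
    coefficients.
    """
    y = train["replicated"].to_numpy()
    if y.min() == y.max():
        raise ValueError("train set has a single outcome class")
    formula = formula or _adapt_formula(train)

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.logit(formula, data=train)
        try:
            res = model.fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            res = None
            separation = True
    if res is not None:
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged or not np.all(np.isfinite(res.bse)) or np.max(np.abs(res.params)) > 50:
            separation = True
    else:
        converged = False

    penalized = False
    if separation and penalize_on_separation:
        res = _ridge_refit(model, train)
        converged, penalized = True, True
    elif res is None:
        raise ValueError("logistic fit failed with perfect separation; no penalized fallback")

    params = np.asarray(res.params, dtype=float)
    names = list(model.exog_names)
    if penalized:
        bse = np.full_like(params, np.nan)
        zvals = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
        ci = np.full((len(params), 2), np.nan)
        llf = _loglik(y, res.predict(train))
    else:
        bse = np.asarray(res.bse, dtype=float)
        zvals = params / bse
        pvals = np.asarray(res.pvalues, dtype=float)
        ci = np.asarray(res.conf_int())
        llf = float(res.llf)

    # closed-form intercept-only log-likelihood (exact null reference)
    pbar = y.mean()
    llnull = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    mcfadden = 1.0 - llf / llnull
    if abs(mcfadden) < 1e-12:
        mcfadden = 0.0

    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": params,
            "se": bse,
            "z": zvals,
            "p_value": pvals,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        }
    )
    return LogisticFit(
        coefficients=coef,
        llf=llf,
        llnull=llnull,
        mcfadden_r2=mcfadden,
        converged=converged,
        separation_flag=separation,
        penalized=penalized,
        formula=formula,
        n_train=len(train),
        _result=res,
    )


def evaluate(
    fit: LogisticFit, test: pd.DataFrame, threshold_rule: str = "youden"
) -> tuple[ModelMetrics, pd.DataFrame]:
    """Score the test half; returns metrics plus the ROC coordinates.

    AUC is the probability that a random replicated SNV scores above a
    random non-replicated one (ties count 1/2), with a DeLong 95% CI.
    Sensitivity/specificity use the Youden-optimal test-ROC threshold by
    default (``threshold_rule="half"`` fixes it at 0.5) with Wilson CIs.
    McFadden's R^2 is carried over from the training fit.
    """
    y = test["replicated"].to_numpy()
    if y.min() == y.max():
        raise ValueError("test set has a single outcome class")
    scores = fit.predict(test)

    auc, lo, hi = delong_auc_ci(y, scores)
    fpr, tpr, thresholds = roc_curve(y, scores)
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})

    if threshold_rule == "youden":
        thr = float(thresholds[np.argmax(tpr - fpr)])
    elif threshold_rule == "half":
        thr = 0.5
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")

    pred = scores >= thr
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_lo, sens_hi = wilson_ci(tp, tp + fn)
    spec_lo, spec_hi = wilson_ci(tn, tn + fp)

    metrics = ModelMetrics(
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        sensitivity=sens,
        sens_ci_low=sens_lo,
        sens_ci_high=sens_hi,
        specificity=spec,
        spec_ci_low=spec_lo,
        spec_ci_high=spec_hi,
        mcfadden_r2=fit.mcfadden_r2,
        threshold=thr,
        threshold_rule=threshold_rule,
        n_test=len(test),
    )
    return metrics, roc


def delong_auc_ci(y: np.ndarray, scores: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong variance-based CI (midrank computation).

    The point estimate equals the Mann–Whitney U statistic normalized by the
    number of (positive, negative) pairs, ties counted 1/2.
    """
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both outcome classes for AUC")
    tz = stats.rankdata(np.concatenate([pos, neg]))
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v01 = (tz[:m] - tx) / n                 # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m           # placement of each negative among positives
    auc = float(v01.mean())
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s01 / m + s10 / n))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    return auc, max(0.0, auc - z * se), min(1.0, auc + z * se)


def _adapt_formula(train: pd.DataFrame) -> str:
    """Default formula, with single-level categorical terms dropped."""
    terms = ["or_discovery"]
    if train["p_category"].nunique() > 1:
        terms.append(f'C(p_category, Treatment(reference="{P_CATEGORY_REFERENCE}"))')
    terms.append("neglog10_p")
    if train["trait_type"].nunique() > 1:
        terms.append("C(trait_type)")
    terms += ["maf", "info", "sample_size_ratio"]
    return "replicated ~ " + " + ".join(terms)


def _ridge_refit(model, train: pd.DataFrame):
    """L2-penalized fallback for separated data, wrapped to mimic predict()."""
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(model.exog)
    y = np.asarray(model.endog).astype(int)
    clf = LogisticRegression(C=1.0, fit_intercept=False, max_iter=2000)
    clf.fit(X, y)

    class _Wrapped:
        params = clf.coef_.ravel()

        @staticmethod
        def predict(data: pd.DataFrame) -> np.ndarray:
            import patsy

            (exog,) = patsy.build_design_matrices([model.data.design_info], data)
            return clf.predict_proba(np.asarray(exog))[:, 1]

    return _Wrapped()


def _loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
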