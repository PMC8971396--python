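"""Association statistics behind model construction and validation.

Contains the generic 2x2 machinery (Pearson chi-squared, two-sided Fisher
exact, cross-product odds ratios with Woolf confidence intervals), the
metric screen, the multiple logistic regression with backward elimination
and Wald testing, per-score-level odds ratios against the score-0 reference,
the score-0 negative control, the logistic probability transform, proportion
enrichment, and a minimum-detectable-OR power calculation.

Conventions: the two-sided Fisher p sums hypergeometric point probabilities
no larger than the observed table's; zero cells in an odds ratio get the
Haldane-Anscombe 0.5 correction; confidence intervals are Woolf
(log OR +/- z * SE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.power import NormalIndPower
from statsmodels.stats.proportion import proportion_effectsize

from .gene_metrics import FINAL_METRICS

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "ModelFit",
    "chi2_test",
    "fisher_exact",
    "odds_ratio_2x2",
    "screen_metrics",
    "BackwardEliminationLogit",
    "fit_backward_model",
    "score_level_or",
    "negative_control_or",
    "probability_transform",
    "proportion_enrichment",
    "min_detectable_or",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of nonnegative integer counts with axis labels."""

    counts: tuple
    row_labels: tuple = ()
    col_labels: tuple = ()

    @classmethod
    def from_array(cls, counts, row_labels=(), col_labels=()) -> "ContingencyTable":
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(arr.dtype, np.integer) and not np.allclose(
            arr, np.round(arr)
        ):
            raise ValueError("counts must be integers")
        return cls(
            tuple(map(tuple, arr.astype(int).tolist())),
            tuple(row_labels),
            tuple(col_labels),
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a named association test on a contingency table or model."""

    statistic_name: str
    statistic: float | None
    p: float | None
    df: int | None = None
    or_estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p": self.p,
            "df": self.df,
            "or": self.or_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "note": self.note,
        }


@dataclass
class ModelFit:
    """Result of the backward-elimination multiple logistic regression."""

    retained_metrics: list[str]
    dropped_metrics: list[tuple[str, str]]
    coefficients: pd.DataFrame  # index metric (+const); coef, se, wald_p, or, ci
    baseline_odds: float

    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coefficients["coef"].drop("const", errors="ignore"))


def _as_2x2(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        arr = table.array
    else:
        arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


def chi2_test(table, yates: bool = False) -> AssociationResult:
    """Pearson chi-squared test of independence on a 2x2 table."""
    arr = _as_2x2(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-squared undefined")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=yates)
    return AssociationResult("chi2", float(stat), float(p), int(dof))


def fisher_exact(table, sided: str = "two_sided") -> AssociationResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p sums the point probabilities of all tables with the
    observed margins whose probability does not exceed the observed one.
    """
    arr = _as_2x2(table)
    alternative = {
        "two_sided": "two-sided",
        "greater": "greater",
        "less": "less",
    }.get(sided)
    if alternative is None:
        raise ValueError(f"unknown sidedness {sided!r}")
    _, p = stats.fisher_exact(arr.astype(int), alternative=alternative)
    a, b = arr[0]
    c, d = arr[1]
    or_est = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else None
    return AssociationResult("fisher", None, float(p), None, or_est)


def odds_ratio_2x2(table, ci_level: float = 0.95) -> AssociationResult:
    """Cross-product odds ratio of a 2x2 table with a Woolf CI and Wald p.

    Any zero cell triggers the Haldane-Anscombe 0.5 correction (noted in the
    result). Equals the exponentiated coefficient of a one-predictor logistic
    regression on the expanded data.
    """
    arr = _as_2x2(table)
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("a zero row/column leaves the odds ratio undefined")
    note = ""
    work = arr.copy()
    if (work == 0).any():
        work = work + 0.5
        note = "haldane_anscombe_0.5"
    a, b, c, d = work.ravel()
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    log_or = math.log(or_est)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return AssociationResult(
        "or_logistic",
        float(log_or / se),
        float(p),
        None,
        float(or_est),
        float(math.exp(log_or - z * se)),
        float(math.exp(log_or + z * se)),
        note,
    )


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _outcome_binary(records: pd.DataFrame) -> pd.Series:
    """CNS (1) vs everything else (0) from an ``outcome`` label column."""
    if "outcome" not in records.columns:
        raise ValueError("records need an 'outcome' column")
    return (records["outcome"].astype(str) == "CNS").astype(int)


def screen_metrics(
    records: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Chi-squared screen of each candidate flag against the CNS outcome.

    Returns one row per metric with the test result and a pass flag
    (p < alpha). Metrics with no variation are failed with reason
    ``degenerate``.
    """
    candidates = list(candidates or FINAL_METRICS)
    y = _outcome_binary(records)
    rows = []
    for metric in candidates:
        flag = records[metric].astype("boolean")
        mask = flag.notna()
        f = flag[mask].astype(bool)
        yy = y[mask]
        if f.nunique() < 2 or yy.nunique() < 2:
            rows.append(
                {"metric": metric, "statistic": None, "p": None, "passed": False,
                 "reason": "degenerate"}
            )
            continue
        table = pd.crosstab(f, yy).reindex(
            index=[False, True], columns=[0, 1], fill_value=0
        )
        res = chi2_test(table.values)
        rows.append(
            {"metric": metric, "statistic": res.statistic, "p": res.p,
             "passed": bool(res.p < alpha), "reason": ""}
        )
    return pd.DataFrame(rows)


class BackwardEliminationLogit:
    """Multiple logistic regression with VIF pruning and backward elimination.

    scikit-learn style estimator. ``fit(X, y)`` takes a DataFrame of binary
    metric columns and a binary outcome. Metrics whose variance inflation
    factor exceeds ``vif_limit`` are dropped first; then the metric with the
    largest Wald p >= ``alpha`` is removed and the model refit until every
    retained coefficient is Wald-significant. Perfectly separating metrics
    are dropped with reason ``separation``.

    Fitted attributes: ``retained_metrics_``, ``dropped_metrics_``,
    ``coefficients_`` (coef, se, wald_p, OR and CI per retained metric),
    ``baseline_odds_`` (exponentiated intercept) and ``result_`` (the final
    statsmodels fit).
    """

    def __init__(self, alpha: float = 0.05, vif_limit: float = 5.0, ci_level: float = 0.95):
        self.alpha = alpha
        self.vif_limit = vif_limit
        self.ci_level = ci_level

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "vif_limit": self.vif_limit, "ci_level": self.ci_level}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    @staticmethod
    def _fit_logit(X: pd.DataFrame, y: np.ndarray):
        design = sm.add_constant(X.astype(float), has_constant="add")
        with np.errstate(all="ignore"):
            return sm.Logit(np.asarray(y, dtype=float), design).fit(disp=0, maxiter=200)

    def fit(self, X: pd.DataFrame, y) -> "BackwardEliminationLogit":
        X = pd.DataFrame(X).astype(float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        dropped: list[tuple[str, str]] = []
        cols = list(X.columns)

        # constant columns cannot be estimated
        for col in list(cols):
            if X[col].nunique() < 2:
                dropped.append((col, "degenerate"))
                cols.remove(col)

        # collinearity pruning: drop the worst VIF until all within limit
        while len(cols) >= 2:
            design = sm.add_constant(X[cols], has_constant="add")
            vifs = pd.Series(
                [variance_inflation_factor(design.values, i + 1) for i in range(len(cols))],
                index=cols,
            )
            worst = vifs.idxmax()
            if np.isfinite(vifs[worst]) and vifs[worst] <= self.vif_limit:
                break
            dropped.append((worst, "collinearity"))
            cols.remove(worst)

        # backward elimination on Wald p-values
        result = None
        while cols:
            try:
                result = self._fit_logit(X[cols], y)
            except Exception:
                # separation or non-convergence: drop the most suspect metric
                sep = self._separating_metric(X[cols], y)
                dropped.append((sep, "separation"))
                cols.remove(sep)
                result = None
                continue
            if not np.isfinite(result.bse.drop("const")).all():
                sep = result.bse.drop("const").idxmax()
                dropped.append((sep, "separation"))
                cols.remove(sep)
                result = None
                continue
            pvals = result.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] >= self.alpha:
                dropped.append((worst, "elimination"))
                cols.remove(worst)
            else:
                break

        self.retained_metrics_ = list(cols)
        self.dropped_metrics_ = dropped
        if cols and result is not None:
            ci = result.conf_int(alpha=1 - self.ci_level)
            self.coefficients_ = pd.DataFrame(
                {
                    "coef": result.params,
                    "se": result.bse,
                    "wald_p": result.pvalues,
                    "or": np.exp(result.params),
                    "ci_low": np.exp(ci[0]),
                    "ci_high": np.exp(ci[1]),
                }
            )
            self.baseline_odds_ = float(np.exp(result.params["const"]))
            self.result_ = result
        else:
            # empty retained set: intercept-only model
            result = self._fit_logit(pd.DataFrame(index=range(len(y))), y)
            self.coefficients_ = pd.DataFrame(
                {
                    "coef": result.params,
                    "se": result.bse,
                    "wald_p": result.pvalues,
                    "or": np.exp(result.params),
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
            self.baseline_odds_ = float(np.exp(result.params["const"]))
            self.result_ = result
        return self

    @staticmethod
    def _separating_metric(X: pd.DataFrame, y: np.ndarray) -> str:
        """Pick the column most consistent with perfect separation."""
        for col in X.columns:
            tab = pd.crosstab(X[col] > 0, pd.Series(y) > 0)
            if (tab.values == 0).any():
                return col
        return X.columns[-1]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design = sm.add_constant(
            pd.DataFrame(X)[self.retained_metrics_].astype(float), has_constant="add"
        )
        p = np.asarray(self.result_.predict(design))
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def to_model_fit(self) -> ModelFit:
        return ModelFit(
            retained_metrics=list(self.retained_metrics_),
            dropped_metrics=list(self.dropped_metrics_),
            coefficients=self.coefficients_.copy(),
            baseline_odds=self.baseline_odds_,
        )


def fit_backward_model(
    records: pd.DataFrame,
    metrics: Sequence[str],
    alpha: float = 0.05,
    vif_limit: float = 5.0,
) -> ModelFit:
    """Backward-elimination logistic fit of the CNS outcome on metric flags.

    Rows with any missing flag among *metrics* are excluded (complete-case).
    """
    metrics = list(metrics)
    if not metrics:
        raise ValueError("need at least one metric")
    flags = records[metrics].astype("boolean")
    mask = flags.notna().all(axis=1)
    X = flags[mask].astype(int)
    y = _outcome_binary(records[mask])
    est = BackwardEliminationLogit(alpha=alpha, vif_limit=vif_limit).fit(X, y)
    return est.to_model_fit()


# ---------------------------------------------------------------------------
# score-level odds ratios
# ---------------------------------------------------------------------------

def _level_table(
    scores: pd.Series, y: pd.Series, members: pd.Series, reference: pd.Series
) -> np.ndarray | None:
    """2x2 of membership (level vs reference) x outcome."""
    a = int((members & (y == 1)).sum())
    b = int((members & (y == 0)).sum())
    c = int((reference & (y == 1)).sum())
    d = int((reference & (y == 0)).sum())
    if a + b == 0 or c + d == 0:
        return None
    return np.array([[a, b], [c, d]])


def score_level_or(
    records: pd.DataFrame,
    reference_level: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-score-level odds of a CNS label relative to score-0 genes.

    *records* needs ``score`` (nullable integer) and ``outcome`` columns.
    Returns one row per level 1..5 plus the pooled ``>=3`` row; a level with
    no genes yields an NA row.
    """
    y = _outcome_binary(records)
    score = records["score"].astype("Int64")
    reference = (score == reference_level).fillna(False)
    if not reference.any():
        raise ValueError(f"reference level {reference_level} is empty")
    rows = []
    levels: list = [1, 2, 3, 4, 5, ">=3"]
    for level in levels:
        if level == ">=3":
            members = (score >= 3).fillna(False)
        else:
            members = (score == level).fillna(False)
        table = _level_table(score, y, members, reference)
        if table is None:
            rows.append({"level": level, "or": None, "ci_low": None,
                         "ci_high": None, "p": None, "n": 0})
            continue
        res = odds_ratio_2x2(table, ci_level)
        rows.append(
            {"level": level, "or": res.or_estimate, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p": res.p, "n": int(members.sum())}
        )
    return pd.DataFrame(rows)


def negative_control_or(records: pd.DataFrame, ci_level: float = 0.95) -> AssociationResult:
    """Odds that a score-0 gene carries a non-CNS (rather than any other) label.

    The control direction of the model: genes untouched by every metric
    should be enriched for non-CNS phenotypes.
    """
    score = records["score"].astype("Int64")
    zero = (score == 0).fillna(False)
    if not zero.any():
        raise ValueError("no score-0 genes")
    non_cns = (records["outcome"].astype(str) == "NON_CNS").astype(int)
    table = np.array(
        [
            [int((zero & (non_cns == 1)).sum()), int((zero & (non_cns == 0)).sum())],
            [int((~zero & (non_cns == 1)).sum()), int((~zero & (non_cns == 0)).sum())],
        ]
    )
    return odds_ratio_2x2(table, ci_level)


def probability_transform(or_value: float, baseline_odds: float) -> float:
    """Map an odds ratio onto the logistic likelihood curve.

    Returns baseline_odds * OR / (1 + baseline_odds * OR): the probability of
    the outcome for the exposed group given the reference group's odds.
    """
    if or_value <= 0 or baseline_odds <= 0:
        raise ValueError("odds ratio and baseline odds must be positive")
    odds = baseline_odds * or_value
    return odds / (1.0 + odds)


def proportion_enrichment(
    subset_hits: int, subset_n: int, genome_hits: int, genome_n: int
) -> AssociationResult:
    """Chi-squared enrichment of a hit rate in a subset vs the genome.

    The subset is removed from the genome complement so the 2x2 cells do not
    overlap: [[subset_hits, subset_misses], [other_hits, other_misses]].
    """
    if subset_n > genome_n or subset_hits > genome_hits:
        raise ValueError("subset counts exceed genome counts")
    if subset_hits > subset_n or genome_hits > genome_n:
        raise ValueError("hits exceed totals")
    table = np.array(
        [
            [subset_hits, subset_n - subset_hits],
            [genome_hits - subset_hits, (genome_n - subset_n) - (genome_hits - subset_hits)],
        ]
    )
    chi = chi2_test(table)
    orr = odds_ratio_2x2(table)
    return AssociationResult(
        "chi2", chi.statistic, chi.p, chi.df, orr.or_estimate, orr.ci_low, orr.ci_high
    )


def min_detectable_or(
    n_exposed: int,
    n_reference: int,
    baseline_rate: float,
    power: float = 0.95,
    alpha: float = 0.05,
) -> float:
    """Smallest OR a two-proportion test detects at the stated power.

    Found by bisection over the OR; the exposed-group rate at a candidate OR
    follows from the baseline odds, and power comes from the normal
    approximation for two independent proportions.
    """
    if not 0 < baseline_rate < 1:
        raise ValueError("baseline rate must be in (0, 1)")
    if n_exposed <= 0 or n_reference <= 0:
        raise ValueError("sample sizes must be positive")
    solver = NormalIndPower()
    odds0 = baseline_rate / (1 - baseline_rate)

    def attained_power(or_value: float) -> float:
        p1 = (odds0 * or_value) / (1 + odds0 * or_value)
        es = proportion_effectsize(p1, baseline_rate)
        return solver.power(
            effect_size=es,
            nobs1=n_exposed,
            alpha=alpha,
            ratio=n_reference / n_exposed,
        )

    lo, hi = 1.0 + 1e-9, 2.0
    while attained_power(hi) < power:
        hi *= 2
        if hi > 1e6:
            raise ValueError("requested power is infeasible at these sizes")
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if attained_power(mid) < power:
            lo = mid
        else:
            hi = mid
    return float(hi)
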