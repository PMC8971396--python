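"""The additive 0-5 gene score and gene-set score profiles.

A gene earns one point per evidence flag among the five final metrics
(de novo burden, exon index, CCR 99th percentile, brain expression,
LOF constraint). Scores map to percentages of the maximum (score x 20)
and genes with a score of at least 3 are "high scoring". A gene missing
any of the five flags is not scorable and carries NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_metrics import FINAL_METRICS, MetricFlags

__all__ = [
    "HIGH_SCORE_MIN",
    "NeuroScore",
    "ScoreProfile",
    "NeuroScorer",
    "score_gene",
    "score_table",
    "profile_gene_set",
    "aggregate_levels",
]

#: Minimum score for the "high scoring" designation.
HIGH_SCORE_MIN = 3


@dataclass(frozen=True)
class NeuroScore:
    """A gene's additive score: points, percent of maximum, high flag."""

    value: int | None
    percent: float | None
    high_scoring: bool

    @classmethod
    def from_value(cls, value: int | None) -> "NeuroScore":
        if value is None:
            return cls(None, None, False)
        if not 0 <= value <= 5:
            raise ValueError(f"score must be in 0..5, got {value}")
        return cls(int(value), 20.0 * value, value >= HIGH_SCORE_MIN)


@dataclass
class ScoreProfile:
    """Score summary for a gene set (e.g. the genes of a recurrent CNV region)."""

    total_genes: int
    scored_genes: int
    counts_by_level: dict
    high_scoring_genes: list[str] = field(default_factory=list)
    max_score: int | None = None
    median_percent: float | None = None
    mean_percent: float | None = None

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "scored_genes": self.scored_genes,
            "counts_by_level": {str(k): v for k, v in self.counts_by_level.items()},
            "high_scoring_genes": list(self.high_scoring_genes),
            "max_score": self.max_score,
            "median_percent": self.median_percent,
            "mean_percent": self.mean_percent,
        }


def score_gene(flags: MetricFlags, lenient: bool = False) -> NeuroScore:
    """Score one gene from its evidence flags.

    In strict mode (default) any missing flag among the five final metrics
    makes the score NA; in lenient mode missing flags count as false.
    """
    final = flags.final()
    if any(f is None for f in final):
        if not lenient:
            return NeuroScore.from_value(None)
        final = tuple(bool(f) for f in final)
    return NeuroScore.from_value(sum(1 for f in final if f))


class NeuroScorer:
    """Transformer mapping evidence-flag columns to scores.

    scikit-learn compatible and stateless: ``transform`` takes a DataFrame
    with the five flag columns (nullable boolean) and returns a DataFrame
    with ``score`` (nullable Int64), ``percent`` and ``high_scoring``.
    """

    def __init__(self, lenient: bool = False):
        self.lenient = lenient

    def get_params(self, deep: bool = True) -> dict:
        return {"lenient": self.lenient}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "NeuroScorer":
        missing = [m for m in FINAL_METRICS if m not in X.columns]
        if missing:
            raise ValueError(f"missing flag columns: {missing}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        flags = X[list(FINAL_METRICS)].astype("boolean")
        if self.lenient:
            flags = flags.fillna(False)
        any_na = flags.isna().any(axis=1)
        score = flags.fillna(False).astype(int).sum(axis=1).astype("Int64")
        score[any_na] = pd.NA
        out = pd.DataFrame(index=X.index)
        out["score"] = score
        out["percent"] = (score * 20).astype("Float64")
        out["high_scoring"] = (score >= HIGH_SCORE_MIN).fillna(False).astype(bool)
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def score_table(records: pd.DataFrame, lenient: bool = False) -> pd.DataFrame:
    """Score every gene in a harmonized flag table.

    *records* needs ``symbol`` plus the five final flag columns; genes marked
    ``incomplete`` are forced to NA. Output is sorted by symbol and carries
    symbol, the flags, score, percent and high_scoring. Duplicate symbols are
    a hard error naming the offenders.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["symbol", *FINAL_METRICS, "score", "percent", "high_scoring"]
        )
    dupes = records["symbol"][records["symbol"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene symbols: {dupes}")
    df = records.sort_values("symbol", kind="mergesort").reset_index(drop=True)
    scored = NeuroScorer(lenient=lenient).fit_transform(df)
    if "incomplete" in df.columns:
        mask = df["incomplete"].fillna(False).astype(bool)
        scored.loc[mask, "score"] = pd.NA
        scored.loc[mask, "percent"] = pd.NA
        scored.loc[mask, "high_scoring"] = False
    keep = ["symbol"] + [c for c in ("ensembl_id",) if c in df.columns]
    out = pd.concat([df[keep + list(FINAL_METRICS)], scored], axis=1)
    if "score_expected" in records.columns:
        # data-fidelity check: precomputed scores must agree with recomputation
        exp = df["score_expected"].astype("Int64")
        bad = df["symbol"][(exp != out["score"]) & exp.notna() & out["score"].notna()]
        if len(bad):
            raise ValueError(f"score mismatch vs input for: {bad.tolist()}")
    return out


def profile_gene_set(symbols: list[str], scores: pd.DataFrame) -> ScoreProfile:
    """Summarize scores over a gene set.

    Genes absent from the scored table count as NA. Median and mean percent
    are over non-NA members only; the even-length median is the mean of the
    two middle values.
    """
    if not symbols:
        raise ValueError("empty gene set")
    table = scores.set_index("symbol")["score"]
    values = [
        (table.get(s) if s in table.index else pd.NA) for s in symbols
    ]
    numeric = np.array(
        [int(v) for v in values if v is not pd.NA and not pd.isna(v)], dtype=float
    )
    counts: dict = {level: 0 for level in range(6)}
    counts["NA"] = 0
    for v in values:
        if v is pd.NA or pd.isna(v):
            counts["NA"] += 1
        else:
            counts[int(v)] += 1
    high = [
        s
        for s, v in zip(symbols, values)
        if v is not pd.NA and not pd.isna(v) and int(v) >= HIGH_SCORE_MIN
    ]
    return ScoreProfile(
        total_genes=len(symbols),
        scored_genes=int((numeric > 0).sum()),
        counts_by_level=counts,
        high_scoring_genes=high,
        max_score=int(numeric.max()) if numeric.size else None,
        median_percent=float(np.median(numeric) * 20) if numeric.size else None,
        mean_percent=float(numeric.mean() * 20) if numeric.size else None,
    )


def aggregate_levels(
    counts_by_level_and_outcome: pd.DataFrame, levels: set[int]
) -> pd.Series:
    """Pool score-level rows of a level-by-outcome count table.

    *counts_by_level_and_outcome* is indexed by score level (0..5); *levels*
    selects the rows to sum element-wise across outcome columns, e.g. pooling
    levels {3, 4, 5} yields the high-scoring row.
    """
    unknown = set(levels) - set(counts_by_level_and_outcome.index)
    if unknown:
        raise ValueError(f"unknown score levels: {sorted(unknown)}")
    return counts_by_level_and_outcome.loc[sorted(levels)].sum(axis=0)
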