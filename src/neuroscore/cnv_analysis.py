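"""Score-aware copy-number-variant annotation and case-control burden testing.

A CNV is paired with every gene whose exons it overlaps by at least one
base pair; the per-CNV score summary (gene count, counts of scored and
high-scoring genes, maximum score level, median and mean score percent)
feeds the cohort battery: Welch t-tests on size/gene-content/score,
per-level maximum-score distribution tests (Fisher when any cell is small),
the >=1-high-scoring-gene odds ratio, sex/inheritance subgroup tests, and
pathogenicity-by-classification linear regression controlling for size.

Within a CNV summary, "scored" genes are those with a non-NA score (a score
of 0 counts as scored); only non-NA scores enter the median and mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
import statsmodels.api as sm

from .assoc_stats import AssociationResult, chi2_test, fisher_exact, odds_ratio_2x2
from .scoring import HIGH_SCORE_MIN, ScoreProfile, profile_gene_set

__all__ = [
    "CNVRecord",
    "CNVScoreSummary",
    "GeneModelIndex",
    "annotate_cnv",
    "annotate_cnvs",
    "drop_unscored_cnvs",
    "filter_aneuploidies",
    "compare_cohorts",
    "max_score_distribution",
    "level_tests_from_counts",
    "high_fraction_from_counts",
    "high_gene_or",
    "high_gene_or_from_counts",
    "subgroup_compare",
    "pathogenicity_regression",
    "region_report",
]

CLASSIFICATION_CODES = {
    "population": 1,
    "likely_benign": 2,
    "vous": 3,
    "pathogenic": 4,
}

#: Maximum-score levels reported in cohort distribution tables, in print order.
LEVEL_ORDER: tuple = (5, 4, 3, 2, 1, 0, "NA")


@dataclass(frozen=True)
class CNVRecord:
    """One copy-number call (coordinates 0-based half-open internally)."""

    chrom: str
    start: int
    end: int
    cnv_type: str = "loss"  # loss | gain
    cohort: str = "case"  # case | control
    sex: str = "unknown"
    inheritance: str = "unknown"
    classification: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")
        if self.cnv_type not in ("loss", "gain"):
            raise ValueError(f"cnv_type must be loss/gain, got {self.cnv_type!r}")
        if self.classification is not None and self.classification not in (1, 2, 3, 4):
            raise ValueError(f"classification code must be 1-4, got {self.classification}")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass
class CNVScoreSummary:
    """Per-CNV score profile."""

    cnv: CNVRecord
    genes: list[str]
    scored_genes: int
    max_level: int | None
    median_percent: float | None
    mean_percent: float | None
    high_count: int
    size_bp: int


class GeneModelIndex:
    """Exon-aware interval index mapping genomic ranges to gene symbols.

    Built once from an exon table (columns ``chrom``, ``start``, ``end``,
    ``gene``; 0-based half-open) and reused across many CNV queries. A
    ``gene_body`` index can be built instead for inputs without exon models.
    """

    def __init__(self, exons: pd.DataFrame, mode: str = "exon"):
        if mode not in ("exon", "gene_body"):
            raise ValueError(f"unknown overlap mode {mode!r}")
        self.mode = mode
        required = {"chrom", "start", "end", "gene"}
        if not required <= set(exons.columns):
            raise ValueError(f"exon table needs columns {sorted(required)}")
        if mode == "gene_body":
            exons = (
                exons.groupby(["chrom", "gene"], as_index=False)
                .agg(start=("start", "min"), end=("end", "max"))
            )
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in exons.groupby("chrom"):
            tree = IntervalTree()
            for s, e, g in zip(sub["start"], sub["end"], sub["gene"]):
                if e > s:
                    tree.addi(int(s), int(e), g)
            self._trees[str(chrom)] = tree
        self.chrom_lengths = {
            str(c): int(sub["end"].max()) for c, sub in exons.groupby("chrom")
        }

    def query(self, chrom: str, start: int, end: int) -> set[str]:
        """Genes with >=1 bp of (exon) overlap with [start, end)."""
        if chrom not in self._trees:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return {iv.data for iv in self._trees[chrom].overlap(start, end)}


def _score_lookup(scores: pd.DataFrame) -> dict:
    s = scores.set_index("symbol")["score"]
    return {
        sym: (None if pd.isna(v) else int(v)) for sym, v in s.items()
    }


def _summarize(genes: Iterable[str], lookup: dict) -> dict:
    genes = sorted(genes)
    vals = [lookup.get(g) for g in genes]
    numeric = np.array([v for v in vals if v is not None], dtype=float)
    return {
        "genes": genes,
        "n_genes": len(genes),
        "scored_genes": int(numeric.size),
        "max_level": int(numeric.max()) if numeric.size else None,
        "median_percent": float(np.median(numeric) * 20) if numeric.size else None,
        "mean_percent": float(numeric.mean() * 20) if numeric.size else None,
        "high_count": int((numeric >= HIGH_SCORE_MIN).sum()),
    }


def annotate_cnv(
    cnv: CNVRecord, gene_models: GeneModelIndex, scores: pd.DataFrame
) -> CNVScoreSummary:
    """Annotate a single CNV with the score profile of its exon-overlapped genes."""
    lookup = _score_lookup(scores)
    info = _summarize(gene_models.query(cnv.chrom, cnv.start, cnv.end), lookup)
    return CNVScoreSummary(
        cnv=cnv,
        genes=info["genes"],
        scored_genes=info["scored_genes"],
        max_level=info["max_level"],
        median_percent=info["median_percent"],
        mean_percent=info["mean_percent"],
        high_count=info["high_count"],
        size_bp=cnv.size_bp,
    )


def annotate_cnvs(
    cnvs: pd.DataFrame,
    gene_models: GeneModelIndex | pd.DataFrame,
    scores: pd.DataFrame,
    mode: str = "exon",
) -> pd.DataFrame:
    """Vectorized CNV annotation.

    *cnvs* needs ``chrom``, ``start``, ``end`` and keeps any extra columns
    (cohort, cnv_type, sex, ...). Returns the input columns plus ``size_bp``,
    ``n_genes``, ``scored_genes``, ``high_count``, ``max_level`` (nullable),
    ``median_percent`` and ``mean_percent``. CNVs overlapping no exon of any
    gene have ``n_genes`` 0 and are typically dropped downstream.
    """
    index = (
        gene_models
        if isinstance(gene_models, GeneModelIndex)
        else GeneModelIndex(gene_models, mode=mode)
    )
    lookup = _score_lookup(scores)
    rows = []
    for chrom, start, end in zip(cnvs["chrom"], cnvs["start"], cnvs["end"]):
        info = _summarize(index.query(str(chrom), int(start), int(end)), lookup)
        info.pop("genes")
        rows.append(info)
    summary = pd.DataFrame(rows, index=cnvs.index)
    out = cnvs.copy()
    out["size_bp"] = out["end"].astype(int) - out["start"].astype(int)
    for col in summary.columns:
        out[col] = summary[col]
    out["max_level"] = out["max_level"].astype("Int64")
    return out


def drop_unscored_cnvs(summaries: pd.DataFrame) -> pd.DataFrame:
    """Remove CNVs whose genes are all unscorable (NA-only) or absent."""
    return summaries[summaries["n_genes"] > 0].copy()


def filter_aneuploidies(
    summaries: pd.DataFrame, chrom_lengths: dict, max_fraction: float = 0.9
) -> pd.DataFrame:
    """Exclude calls covering more than *max_fraction* of their chromosome."""
    frac = np.array(
        [
            (e - s) / chrom_lengths[str(c)]
            for c, s, e in zip(summaries["chrom"], summaries["start"], summaries["end"])
        ]
    )
    dropped = int((frac > max_fraction).sum())
    if dropped:
        warnings.warn(f"excluded {dropped} aneuploidy-scale CNVs", stacklevel=2)
    return summaries[frac <= max_fraction].copy()


# ---------------------------------------------------------------------------
# cohort comparisons
# ---------------------------------------------------------------------------

_T_TEST_VARS = ("size_bp", "n_genes", "scored_genes", "mean_percent", "median_percent")


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=False, nan_policy="omit")
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    variables: Sequence[str] = _T_TEST_VARS,
    bonferroni_tests: int | None = None,
) -> pd.DataFrame:
    """Welch two-sided t-tests between case and control CNVs per loss/gain stratum.

    Defaults to the five per-CNV measures (size, total genes, scored genes,
    mean and median score percent) in both strata; the Bonferroni alpha is
    0.05 divided by the scheduled test count (len(variables) x 2 strata
    unless overridden).
    """
    if cases.empty or controls.empty:
        raise ValueError("both cohorts must be nonempty")
    n_tests = bonferroni_tests or len(variables) * 2
    alpha = 0.05 / n_tests
    rows = []
    for stratum in ("loss", "gain"):
        ca = cases[cases["cnv_type"] == stratum]
        co = controls[controls["cnv_type"] == stratum]
        for var in variables:
            if ca.empty or co.empty:
                warnings.warn(f"stratum {stratum} empty in one cohort; skipped", stacklevel=2)
                continue
            a = pd.to_numeric(ca[var], errors="coerce").to_numpy(dtype=float)
            b = pd.to_numeric(co[var], errors="coerce").to_numpy(dtype=float)
            t, p = _welch(a, b)
            rows.append(
                {
                    "test": var,
                    "stratum": stratum,
                    "case_mean": float(np.nanmean(a)),
                    "control_mean": float(np.nanmean(b)),
                    "t": t,
                    "p": p,
                    "bonferroni_alpha": alpha,
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def _max_level_counts(summaries: pd.DataFrame) -> pd.Series:
    """Counts of CNVs by maximum gene score level (NA = no scorable gene)."""
    levels = summaries["max_level"]
    counts = {lvl: 0 for lvl in LEVEL_ORDER}
    for v in levels:
        counts["NA" if pd.isna(v) else int(v)] += 1
    return pd.Series(counts)


def level_tests_from_counts(
    case_counts: pd.Series,
    control_counts: pd.Series,
    fisher_rule: str = "cell_le_5",
    fisher_cutoff: int = 5,
    bonferroni_alpha: float = 0.004,
) -> pd.DataFrame:
    """Per-level cohort x (max level = L vs != L) tests from count vectors.

    Fisher's exact test is used when any observed cell of the 2x2 is at most
    *fisher_cutoff* (or, under the ``expected`` rule, when any expected count
    is), chi-squared otherwise.
    """
    n_case = int(case_counts.sum())
    n_control = int(control_counts.sum())
    rows = []
    for level in case_counts.index:
        a = int(case_counts[level])
        c = int(control_counts[level])
        table = np.array([[a, n_case - a], [c, n_control - c]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            rows.append(
                {"level": level, "case_n": a, "case_pct": 100 * a / n_case,
                 "control_n": c, "control_pct": 100 * c / n_control,
                 "test": "degenerate", "p": None, "significant": False}
            )
            continue
        if fisher_rule == "expected":
            expected = stats.contingency.expected_freq(table)
            use_fisher = expected.min() <= fisher_cutoff
        else:
            use_fisher = table.min() <= fisher_cutoff
        res = fisher_exact(table) if use_fisher else chi2_test(table)
        rows.append(
            {
                "level": level,
                "case_n": a,
                "case_pct": 100 * a / n_case,
                "control_n": c,
                "control_pct": 100 * c / n_control,
                "test": res.statistic_name,
                "p": res.p,
                "significant": bool(res.p < bonferroni_alpha),
            }
        )
    return pd.DataFrame(rows)


def max_score_distribution(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    fisher_rule: str = "cell_le_5",
    bonferroni_alpha: float = 0.004,
) -> dict[str, pd.DataFrame]:
    """Distribution of the highest-scoring gene per CNV, tested per level.

    Returns one table per stratum (loss/gain) in the print order 5..0, NA.
    The default Bonferroni alpha 0.004 corresponds to 14 tests (7 levels x 2
    CNV classes).
    """
    out = {}
    for stratum in ("loss", "gain"):
        case_counts = _max_level_counts(cases[cases["cnv_type"] == stratum])
        control_counts = _max_level_counts(controls[controls["cnv_type"] == stratum])
        out[stratum] = level_tests_from_counts(
            case_counts, control_counts, fisher_rule, bonferroni_alpha=bonferroni_alpha
        )
    return out


def high_fraction_from_counts(counts: pd.Series) -> float:
    """Fraction of CNVs whose maximum gene score is high (>= 3), from level counts."""
    high = sum(int(counts[lvl]) for lvl in (3, 4, 5) if lvl in counts.index)
    return high / int(counts.sum())


def high_gene_or(
    cases: pd.DataFrame, controls: pd.DataFrame, ci_level: float = 0.95
) -> AssociationResult:
    """Odds ratio for case CNVs carrying >=1 high-scoring gene, pooled strata.

    CNVs with no scorable gene are excluded before forming the 2x2.
    """
    ca = cases[cases["scored_genes"] > 0]
    co = controls[controls["scored_genes"] > 0]
    table = np.array(
        [
            [int((ca["high_count"] >= 1).sum()), int((ca["high_count"] < 1).sum())],
            [int((co["high_count"] >= 1).sum()), int((co["high_count"] < 1).sum())],
        ]
    )
    return odds_ratio_2x2(table, ci_level)


def high_gene_or_from_counts(
    case_counts_by_stratum: dict[str, pd.Series],
    control_counts_by_stratum: dict[str, pd.Series],
    ci_level: float = 0.95,
) -> AssociationResult:
    """Same odds ratio computed from per-level maximum-score count vectors.

    A CNV's maximum level is >= 3 exactly when it carries a high-scoring
    gene; NA rows (no scorable gene) are excluded from the totals.
    """

    def pool(counts_by_stratum):
        high = total = 0
        for counts in counts_by_stratum.values():
            high += sum(int(counts[lvl]) for lvl in (3, 4, 5) if lvl in counts.index)
            total += int(counts.sum()) - (int(counts["NA"]) if "NA" in counts.index else 0)
        return high, total

    ch, ct = pool(case_counts_by_stratum)
    oh, ot = pool(control_counts_by_stratum)
    table = np.array([[ch, ct - ch], [oh, ot - oh]])
    return odds_ratio_2x2(table, ci_level)


def subgroup_compare(cases: pd.DataFrame, by: str) -> pd.DataFrame:
    """Welch t-tests on score measures between case subgroups.

    ``by='sex'`` compares male vs female probands; ``by='inheritance'`` pools
    maternal and paternal calls as "inherited" and compares them with de novo
    calls. CNVs with an unknown grouping value are excluded (their count is
    reported in the ``excluded`` column).
    """
    if by == "sex":
        groups = {"male": cases["sex"] == "male", "female": cases["sex"] == "female"}
    elif by == "inheritance":
        groups = {
            "inherited": cases["inheritance"].isin(["maternal", "paternal"]),
            "de_novo": cases["inheritance"] == "de_novo",
        }
    else:
        raise ValueError(f"unknown grouping {by!r}")
    (name_a, mask_a), (name_b, mask_b) = groups.items()
    excluded = int((~(mask_a | mask_b)).sum())
    rows = []
    for var in ("mean_percent", "median_percent", "high_count"):
        a = pd.to_numeric(cases.loc[mask_a, var], errors="coerce").dropna().to_numpy()
        b = pd.to_numeric(cases.loc[mask_b, var], errors="coerce").dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"subgroup too small for {var}; skipped", stacklevel=2)
            continue
        t, p = _welch(a, b)
        rows.append(
            {
                "test": var,
                "group_a": name_a,
                "group_b": name_b,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t": t,
                "p": p,
                "excluded": excluded,
            }
        )
    return pd.DataFrame(rows)


def pathogenicity_regression(cases: pd.DataFrame) -> pd.DataFrame:
    """OLS of gene-content measures on the 1-4 pathogenicity code, size-adjusted.

    For each of high-scoring gene count, low-scoring (scored but not high)
    count, non-scored count and median score percent, fits
    outcome ~ classification + size_bp and reports the classification slope.
    """
    df = cases.dropna(subset=["classification"]).copy()
    codes = pd.to_numeric(df["classification"], errors="coerce")
    if codes.nunique() < 2:
        raise ValueError("need at least two classification levels")
    df["low_count"] = df["scored_genes"] - df["high_count"]
    df["unscored_count"] = df["n_genes"] - df["scored_genes"]
    rows = []
    for outcome in ("high_count", "low_count", "unscored_count", "median_percent"):
        y = pd.to_numeric(df[outcome], errors="coerce")
        X = sm.add_constant(
            pd.DataFrame({"classification": codes, "size_bp": df["size_bp"].astype(float)})
        )
        mask = y.notna()
        fit = sm.OLS(y[mask], X[mask]).fit()
        rows.append(
            {
                "outcome": outcome,
                "beta": float(fit.params["classification"]),
                "se": float(fit.bse["classification"]),
                "p": float(fit.pvalues["classification"]),
                "size_beta": float(fit.params["size_bp"]),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def region_report(
    region: tuple[str, int, int],
    segments: dict[str, tuple[int, int]],
    gene_models: GeneModelIndex,
    scores: pd.DataFrame,
) -> tuple[dict[str, ScoreProfile], pd.DataFrame]:
    """Score profile of a recurrent-CNV region and its breakpoint segments.

    *segments* maps segment names to (start, end) within the region. Returns
    the per-segment (plus whole-region) profiles and a per-gene table
    (gene, score, high flag) for rendering.
    """
    chrom, rstart, rend = region
    for name, (s, e) in segments.items():
        if s < rstart or e > rend:
            raise ValueError(f"segment {name} outside the region")
    lookup = _score_lookup(scores)
    profiles: dict[str, ScoreProfile] = {}
    targets = {"region": (rstart, rend), **segments}
    for name, (s, e) in targets.items():
        genes = sorted(gene_models.query(chrom, s, e))
        if not genes:
            warnings.warn(f"segment {name} covers no genes", stacklevel=2)
            profiles[name] = ScoreProfile(
                total_genes=0, scored_genes=0,
                counts_by_level={**{i: 0 for i in range(6)}, "NA": 0},
            )
            continue
        profiles[name] = profile_gene_set(genes, scores)
    region_genes = sorted(gene_models.query(chrom, rstart, rend))
    table = pd.DataFrame(
        {
            "gene": region_genes,
            "score": [lookup.get(g) for g in region_genes],
        }
    )
    table["score"] = table["score"].astype("Int64")
    table["high_scoring"] = (table["score"] >= HIGH_SCORE_MIN).fillna(False)
    return profiles, table
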