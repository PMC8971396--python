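"""Reproducible validation experiments over the synthetic study conditions.

Three batteries used by the test suite and the acceptance script:

* exhaustive agreement of the Fisher exact test with hypergeometric
  enumeration over every 2x2 table with small margins;
* parameter recovery of the five true metrics by the screening plus
  backward-elimination pipeline over replicate synthetic genomes;
* recovery of a configured case/control high-gene enrichment odds ratio
  over replicate simulated CNV cohorts at clinical-cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .assoc_stats import fisher_exact, fit_backward_model, screen_metrics
from .cnv_analysis import GeneModelIndex, annotate_cnvs, drop_unscored_cnvs, high_gene_or
from .gene_metrics import CANDIDATE_METRICS, FINAL_METRICS
from .scoring import score_table
from .synthetic_data import (
    CNVSimConfig,
    GenomeSimConfig,
    simulate_cnv_cohorts,
    simulate_gene_models,
    simulate_genome,
)

__all__ = [
    "fisher_enumeration_check",
    "backward_elimination_recovery",
    "high_gene_or_recovery",
]

_MODULUS = 2**31 - 1


def _enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing point probabilities <= the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def point(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-9))


def fisher_enumeration_check(max_margin: int = 12) -> dict:
    """Compare fisher_exact with enumeration on every table with margins <= max_margin.

    Tables with a zero margin are skipped (the test is undefined there).
    Returns the table count, maximum absolute p difference, and the fraction
    agreeing within 1e-9.
    """
    n_tables = 0
    max_diff = 0.0
    agree = 0
    m = max_margin
    for a in range(m + 1):
        for b in range(m - a + 1):
            for c in range(m - a + 1):
                for d in range(min(m - b, m - c) + 1):
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    n_tables += 1
                    diff = abs(
                        fisher_exact([[a, b], [c, d]]).p - _enumeration_p(a, b, c, d)
                    )
                    max_diff = max(max_diff, diff)
                    agree += diff <= 1e-9
    return {
        "n_tables": n_tables,
        "max_abs_diff": max_diff,
        "agreement_rate": agree / n_tables,
    }


@dataclass
class RecoveryResult:
    rate: float
    n_replicates: int
    detail: dict


def backward_elimination_recovery(
    n_replicates: int = 100, n_genes: int = 15_000, seed: int = 0
) -> RecoveryResult:
    """Fraction of replicate genomes whose fit retains all five true metrics.

    Each replicate simulates a labeled genome under the default conditions,
    screens the nine candidates at p < 0.05, and runs the backward
    elimination on the survivors. Also reports the mean log-OR estimation
    bias per true metric across replicates.
    """
    truth = {m: v for m, v in zip(
        FINAL_METRICS, np.log([2.2, 1.9, 1.8, 1.7, 1.4])
    )}
    successes = 0
    bias: dict[str, list[float]] = {m: [] for m in FINAL_METRICS}
    cfg = GenomeSimConfig(n_genes=n_genes)
    for rep in range(n_replicates):
        genome = simulate_genome(cfg, seed=(seed * 100003 + rep) % _MODULUS)
        screen = screen_metrics(genome, CANDIDATE_METRICS)
        passed = screen.loc[screen["passed"], "metric"].tolist()
        fit = fit_backward_model(genome, passed)
        if set(FINAL_METRICS) <= set(fit.retained_metrics):
            successes += 1
            for m in FINAL_METRICS:
                bias[m].append(fit.coefficients.loc[m, "coef"] - truth[m])
    mean_bias = {m: float(np.mean(v)) if v else float("nan") for m, v in bias.items()}
    return RecoveryResult(
        rate=successes / n_replicates,
        n_replicates=n_replicates,
        detail={"mean_log_or_bias": mean_bias,
                "max_abs_bias": max(abs(b) for b in mean_bias.values())},
    )


def high_gene_or_recovery(
    n_replicates: int = 100,
    or_target: float = 9.0,
    seed: int = 0,
    cnv_config: CNVSimConfig | None = None,
) -> RecoveryResult:
    """Coverage of a configured cohort enrichment OR by the estimated 95% CI.

    One synthetic genome and exon map are built once; each replicate draws
    fresh case/control CNV cohorts at clinical-cohort sizes, annotates them,
    and estimates the odds ratio for case CNVs carrying a high-scoring gene.
    """
    genome = simulate_genome(seed=seed % _MODULUS)
    scored = score_table(genome)
    genes, exons = simulate_gene_models(
        len(genome), seed=seed % _MODULUS, symbols=genome["symbol"].tolist()
    )
    index = GeneModelIndex(exons)
    cfg = cnv_config or CNVSimConfig(high_gene_or=or_target)
    covered = 0
    estimates = []
    for rep in range(n_replicates):
        cnvs = simulate_cnv_cohorts(
            cfg, genes, scored, seed=(seed * 100003 + 7 * rep + 1) % _MODULUS,
            exons=exons,
        )
        ann = drop_unscored_cnvs(annotate_cnvs(cnvs, index, scored))
        res = high_gene_or(ann[ann["cohort"] == "case"], ann[ann["cohort"] == "control"])
        estimates.append(res.or_estimate)
        covered += int(res.ci_low <= or_target <= res.ci_high)
    return RecoveryResult(
        rate=covered / n_replicates,
        n_replicates=n_replicates,
        detail={"mean_or": float(np.mean(estimates)),
                "or_target": or_target},
    )
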