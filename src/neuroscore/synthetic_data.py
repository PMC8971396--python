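"""Synthetic genomes, labeled outcomes, CNV cohorts and ortholog tables.

The generators emulate the study conditions of the scoring model so every
analysis stage is testable without external downloads:

* a gene universe of 19,601 protein-coding genes whose five evidence-flag
  marginal frequencies match the source-database gene counts (487 de novo,
  4636 index, 1444 CCR-99, 6069 brain-expressed, 2896 LOF-constrained);
* a CNS outcome drawn from a logistic model whose per-metric odds ratios
  default to the fitted values (2.2, 1.9, 1.8, 1.7, 1.4) with a score-0
  baseline CNS rate of 715/10461;
* audit metrics that are marginally but not conditionally informative
  (CCR-95 contains CCR-99; the missense flag sits inside the LOF flag; the
  burden flags overlap the index flag), so the metric screen passes them and
  backward elimination removes them;
* raw metric values back-filled consistently with each flag so the
  binarizers round-trip exactly;
* case/control CNV cohorts placed on a synthetic exon map, sized like the
  clinical cohorts (case losses/gains 344/419 kb on average, controls
  104/244 kb) and tilted toward high-scoring genes at a configurable odds
  ratio (a case CNV without a high-scoring gene is kept with probability
  1/OR);
* mouse-ortholog phenotype tables with configurable per-class enrichment.

Packaged fixtures encode printed per-level count tables and two
recurrent-region gene lists; the region fixtures carry synthetic per-gene
score stand-ins (only their counts are meaningful).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .gene_metrics import FINAL_METRICS, MetricBinarizer
from .ortholog_analysis import DEFAULT_CLASS_MAP, DEFAULT_PHENOTYPES

__all__ = [
    "GenomeSimConfig",
    "CNVSimConfig",
    "simulate_genome",
    "simulate_gene_models",
    "simulate_cnv_cohorts",
    "simulate_ortholog_table",
    "load_fixture",
    "FIXTURE_NAMES",
]

_TABLE1_TOTALS = {
    "de_novo": 487,
    "index": 4636,
    "ccr99": 1444,
    "gtex": 6069,
    "gnomad_lof": 2896,
    "ccr95": 7049,
    "gnomad_mis": 144,
    "coe1": 3116,
    "coe2": 3732,
}
_N_GENES = 19601


@dataclass
class GenomeSimConfig:
    """Conditions for the synthetic gene universe."""

    n_genes: int = _N_GENES
    #: marginal frequency of each final metric flag
    metric_freqs: dict = field(
        default_factory=lambda: {
            m: _TABLE1_TOTALS[m] / _N_GENES for m in FINAL_METRICS
        }
    )
    #: per-metric log odds of a CNS label (defaults exp to 2.2/1.9/1.8/1.7/1.4)
    metric_log_odds: dict = field(
        default_factory=lambda: {
            "de_novo": np.log(2.2),
            "index": np.log(1.9),
            "ccr99": np.log(1.8),
            "gtex": np.log(1.7),
            "gnomad_lof": np.log(1.4),
        }
    )
    #: latent-Gaussian pairwise correlation between metric flags
    correlation: float = 0.0
    #: CNS probability for a gene with no flag set
    baseline_prevalence: float = 715 / 10461
    #: fraction of genes missing one metric source (scored NA)
    missing_rate: float = 842 / _N_GENES
    #: include the marginally-informative audit metrics
    audit_metrics: bool = True
    #: among non-CNS genes: fraction labeled NON_CNS / ABSENT
    non_cns_rate: float = 0.13
    absent_rate: float = 0.21
    #: odds multiplier for a NON_CNS label among genes with no flag set
    #: (zero-scoring genes skew toward non-CNS conditions)
    non_cns_zero_odds: float = 1.7


def _latent_flags(rng: np.random.Generator, n: int, freqs: dict, rho: float) -> pd.DataFrame:
    """Correlated binary flags by thresholding an equicorrelated Gaussian."""
    k = len(freqs)
    if not -1.0 / max(k - 1, 1) < rho < 1.0:
        raise ValueError(f"infeasible equicorrelation {rho} for {k} flags")
    if rho == 0:
        z = rng.standard_normal((n, k))
    else:
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, k))
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    from scipy.stats import norm

    thresholds = norm.ppf([1 - f for f in freqs.values()])
    return pd.DataFrame(z > thresholds, columns=list(freqs.keys()))


def simulate_genome(
    config: GenomeSimConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Generate a labeled synthetic gene table.

    Returns one row per gene with identifiers, raw metric values, the
    evidence flags recomputed from those raw values, ``incomplete`` (missing
    at >=1 source) and the outcome label.
    """
    cfg = config or GenomeSimConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_genes

    flags = _latent_flags(rng, n, cfg.metric_freqs, cfg.correlation)

    # outcome from the logistic model
    eta = np.log(cfg.baseline_prevalence / (1 - cfg.baseline_prevalence))
    eta = eta + sum(
        cfg.metric_log_odds.get(m, 0.0) * flags[m].to_numpy(float)
        for m in cfg.metric_freqs
    )
    p_cns = 1 / (1 + np.exp(-eta))
    cns = rng.random(n) < p_cns
    # non-CNS label odds tilted toward genes no metric touched
    zero_flag = ~flags.any(axis=1).to_numpy()
    odds_non = cfg.non_cns_rate / (1 - cfg.non_cns_rate)
    p_non = np.where(
        zero_flag,
        odds_non * cfg.non_cns_zero_odds / (1 + odds_non * cfg.non_cns_zero_odds),
        cfg.non_cns_rate,
    )
    u = rng.random(n)
    absent_given_rest = cfg.absent_rate / (1 - cfg.non_cns_rate)
    outcome = np.where(
        cns,
        "CNS",
        np.where(
            u < p_non,
            "NON_CNS",
            np.where(
                (u - p_non) / (1 - p_non) < absent_given_rest, "ABSENT", "NO_PHENOTYPE"
            ),
        ),
    )

    df = pd.DataFrame(
        {
            "symbol": [f"G{i:05d}" for i in range(n)],
            "ensembl_id": [f"ENSG{i:011d}" for i in range(n)],
        }
    )

    # raw values back-filled so the binarizers reproduce the drawn flags
    lof = flags["gnomad_lof"].to_numpy()
    df["oe_lof_upper"] = np.where(
        lof, rng.uniform(0.01, 0.345, n), rng.uniform(0.345, 2.0, n)
    )
    ccr99 = flags["ccr99"].to_numpy()
    # non-ccr99 genes land in [95,99) often enough to hit the CCR-95 marginal
    p95_extra = (_TABLE1_TOTALS["ccr95"] - _TABLE1_TOTALS["ccr99"]) / (
        _N_GENES - _TABLE1_TOTALS["ccr99"]
    )
    in_shell = rng.random(n) < p95_extra
    df["ccr_max_percentile"] = np.where(
        ccr99,
        rng.uniform(99.0, 100.0, n),
        np.where(in_shell, rng.uniform(95.0, 99.0, n), rng.uniform(0.0, 95.0, n)),
    )
    gtex = flags["gtex"].to_numpy()
    target_median = np.where(gtex, rng.uniform(10.0, 80.0, n), rng.uniform(0.0, 10.0, n))
    tissue = rng.lognormal(0.0, 0.5, size=(n, 13))
    tissue *= (target_median / np.median(tissue, axis=1))[:, None]
    for i in range(13):
        df[f"brain_tpm_{i}"] = tissue[:, i]
    dn = flags["de_novo"].to_numpy()
    df["denovo_count"] = np.where(
        dn, 10 + rng.poisson(5.0, n), np.minimum(rng.poisson(0.5, n), 9)
    )
    df["index_flag"] = flags["index"].to_numpy()

    if cfg.audit_metrics:
        # missense constraint nested inside LOF constraint
        mis_rate = _TABLE1_TOTALS["gnomad_mis"] / _TABLE1_TOTALS["gnomad_lof"]
        mis = lof & (rng.random(n) < mis_rate)
        df["oe_mis_upper"] = np.where(
            mis, rng.uniform(0.01, 0.345, n), rng.uniform(0.345, 2.0, n)
        )
        # CNV-burden p-values overlapping the index flag: indexed genes are
        # enriched below 0.01, the 0.01-0.02 shell is independent
        # stricter burden cutoff enriched among index genes; the looser
        # cutoff's extra genes drawn from non-index genes only, so the looser
        # flag's marginal association is diluted toward the screen threshold
        p_coe1 = _TABLE1_TOTALS["coe1"] / _N_GENES
        boost = 2.2
        base1 = p_coe1 / (1 + (boost - 1) * cfg.metric_freqs["index"])
        coe1 = rng.random(n) < np.where(flags["index"], boost * base1, base1)
        shell = (_TABLE1_TOTALS["coe2"] - _TABLE1_TOTALS["coe1"]) / _N_GENES
        eligible = ~coe1 & ~flags["index"].to_numpy()
        p_shell = shell / max(eligible.mean(), 1e-9)
        in_shell2 = eligible & (rng.random(n) < p_shell)
        df["coe_p"] = np.where(
            coe1,
            rng.uniform(1e-4, 0.01, n),
            np.where(in_shell2, rng.uniform(0.0100001, 0.02, n), rng.uniform(0.0200001, 1.0, n)),
        )

    # recompute flags from raw values (round-trip by construction)
    out_flags = MetricBinarizer().fit_transform(df)
    for col in out_flags.columns:
        df[col] = out_flags[col]

    # missingness: drop one random final metric for a fraction of genes
    df["incomplete"] = False
    n_missing = int(round(cfg.missing_rate * n))
    if n_missing:
        which_gene = rng.choice(n, size=n_missing, replace=False)
        which_metric = rng.integers(0, len(FINAL_METRICS), size=n_missing)
        for g, m in zip(which_gene, which_metric):
            df.loc[g, FINAL_METRICS[m]] = pd.NA
        df.loc[which_gene, "incomplete"] = True

    df["outcome"] = outcome
    return df


def simulate_gene_models(
    n_genes: int,
    seed: int = 0,
    n_chroms: int = 20,
    mean_gene_bp: int = 30_000,
    mean_gap_bp: int = 70_000,
    max_exons: int = 10,
    symbols: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay non-overlapping genes with exons along synthetic chromosomes.

    Returns (genes, exons) tables with 0-based half-open coordinates. Every
    gene's first and last exon touch the gene boundaries so a CNV reaching
    into a gene body generally reaches an exon, mirroring dense clinical
    exon models.
    """
    rng = np.random.default_rng(seed)
    if symbols is None:
        symbols = [f"G{i:05d}" for i in range(n_genes)]
    per_chrom = int(np.ceil(n_genes / n_chroms))
    gene_rows = []
    exon_rows = []
    g = 0
    for c in range(n_chroms):
        pos = 10_000
        chrom = f"chr{c + 1}"
        for _ in range(per_chrom):
            if g >= n_genes:
                break
            gap = int(rng.exponential(mean_gap_bp)) + 1_000
            length = int(rng.exponential(mean_gene_bp)) + 2_000
            start = pos + gap
            end = start + length
            gene_rows.append((chrom, start, end, symbols[g]))
            n_ex = int(rng.integers(2, max_exons + 1))
            bounds = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2, replace=False))
            edges = np.concatenate([[0], bounds, [length]])
            for e in range(n_ex):
                s, t = int(edges[2 * e]), int(edges[2 * e + 1])
                if t <= s:
                    t = s + 1
                exon_rows.append((chrom, start + s, start + t, symbols[g]))
            pos = end
            g += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene"])
    return genes, exons


@dataclass
class CNVSimConfig:
    """Conditions for the synthetic case/control CNV cohorts.

    Defaults mirror the clinical cohorts: 835/1357 case loss/gain calls,
    2547/1862 control loss/gain calls, log-normal sizes with the cohorts'
    mean sizes, and a 9-fold case enrichment for CNVs containing at least
    one high-scoring gene.
    """

    n_case_loss: int = 835
    n_case_gain: int = 1357
    n_control_loss: int = 2547
    n_control_gain: int = 1862
    mean_size: dict = field(
        default_factory=lambda: {
            ("case", "loss"): 344_000.0,
            ("case", "gain"): 419_000.0,
            ("control", "loss"): 104_000.0,
            ("control", "gain"): 244_000.0,
        }
    )
    size_sigma: float = 0.8
    high_gene_or: float = 9.0
    male_fraction: float = 1724 / 2192
    inheritance_fracs: dict = field(
        default_factory=lambda: {
            "maternal": 43 / 2192,
            "paternal": 35 / 2192,
            "de_novo": 33 / 2192,
        }
    )
    classification_fracs: dict = field(
        default_factory=lambda: {
            "population": 2195 / 2478,
            "likely_benign": 39 / 2478,
            "vous": 148 / 2478,
            "pathogenic": 96 / 2478,
        }
    )


class _FastGeneMap:
    """Sorted-array overlap lookup for the non-overlapping synthetic gene map.

    When exon models are supplied, a gene counts only if the query interval
    overlaps at least one of its exons; fully contained genes always qualify,
    so only the (at most two) boundary genes need an exon check.
    """

    def __init__(self, genes: pd.DataFrame, scores: pd.DataFrame,
                 exons: pd.DataFrame | None = None):
        score = scores.set_index("symbol")["score"]
        exon_lookup: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if exons is not None:
            for gene, sub in exons.groupby("gene"):
                exon_lookup[gene] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        self.chroms = {}
        for chrom, sub in genes.groupby("chrom"):
            sub = sub.sort_values("start")
            sc = score.reindex(sub["gene"]).to_numpy(dtype="float64", na_value=np.nan)
            high = np.nan_to_num(sc, nan=-1) >= 3
            ex = (
                [exon_lookup.get(g, (None, None)) for g in sub["gene"]]
                if exons is not None
                else None
            )
            self.chroms[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                high,
                np.concatenate([[0], np.cumsum(high)]),
                ex,
            )

    def n_genes_and_high(self, chrom: str, start: int, end: int) -> tuple[int, bool]:
        starts, ends, high, high_cum, ex = self.chroms[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if j <= i:
            return 0, False
        if ex is None:
            return j - i, bool(high_cum[j] - high_cum[i] > 0)
        n = j - i
        hh = bool(high_cum[j] - high_cum[i] > 0)
        dropped_high = 0
        for k in {i, j - 1}:
            if starts[k] >= start and ends[k] <= end:
                continue  # fully contained: exons necessarily overlap
            ex_s, ex_e = ex[k]
            if ex_s is None or not ((ex_s < end) & (ex_e > start)).any():
                n -= 1
                dropped_high += int(high[k])
        if dropped_high and hh:
            hh = bool(high_cum[j] - high_cum[i] - dropped_high > 0)
        return n, hh


def simulate_cnv_cohorts(
    config: CNVSimConfig | None = None,
    genes: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
    seed: int = 0,
    exons: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Place case and control CNVs on the synthetic gene map.

    Every emitted CNV overlaps at least one gene (calls touching no gene are
    redrawn, as gene-free calls are excluded upstream of scoring). The case
    cohort is tilted so its odds of containing a high-scoring gene are
    ``high_gene_or`` times the realized control odds: a pilot batch of
    untilted case-style draws estimates the case baseline (case CNVs are
    larger, so placement alone already enriches them), and candidate case
    draws are then accepted with probabilities that close the remaining gap.

    Returns one table with columns chrom/start/end/cnv_type/cohort/sex/
    inheritance/classification.
    """
    cfg = config or CNVSimConfig()
    if genes is None or scores is None:
        raise ValueError("need the synthetic gene map and scored table")
    if cfg.high_gene_or <= 0:
        raise ValueError("enrichment OR must be positive")
    rng = np.random.default_rng(seed)
    fast = _FastGeneMap(genes, scores, exons)
    any_high = any(c[3][-1] > 0 for c in fast.chroms.values())
    if not any_high and cfg.high_gene_or != 1:
        raise ValueError("no high-scoring genes on the map: enrichment OR unreachable")
    chrom_names = list(fast.chroms.keys())
    chrom_ends = np.array([fast.chroms[c][1][-1] for c in chrom_names], dtype=float)
    chrom_p = chrom_ends / chrom_ends.sum()

    def draw(cohort: str, cnv_type: str):
        """One placed CNV overlapping >=1 gene; returns (chrom, start, end, has_high)."""
        mean = cfg.mean_size[(cohort, cnv_type)]
        mu = np.log(mean) - cfg.size_sigma**2 / 2
        for _ in range(100_000):
            ci = rng.choice(len(chrom_names), p=chrom_p)
            chrom = chrom_names[ci]
            size = max(1_000, int(rng.lognormal(mu, cfg.size_sigma)))
            start = int(rng.integers(0, max(1, int(chrom_ends[ci]) - 1)))
            end = start + size
            n_genes_hit, has_high = fast.n_genes_and_high(chrom, start, end)
            if n_genes_hit > 0:
                return chrom, start, end, has_high
        raise RuntimeError("CNV placement not converging")

    jobs = {
        ("case", "loss"): cfg.n_case_loss,
        ("case", "gain"): cfg.n_case_gain,
        ("control", "loss"): cfg.n_control_loss,
        ("control", "gain"): cfg.n_control_gain,
    }

    # controls: accept every placed draw
    control_rows = []
    control_high = 0
    for cnv_type in ("loss", "gain"):
        for _ in range(jobs[("control", cnv_type)]):
            chrom, start, end, hh = draw("control", cnv_type)
            control_rows.append((chrom, start, end, cnv_type, "control"))
            control_high += hh
    n_control = len(control_rows)
    if control_high in (0, n_control):
        if cfg.high_gene_or != 1:
            raise ValueError(
                "control high-gene rate degenerate: enrichment OR unreachable"
            )
        keep_high = keep_plain = 1.0  # no high genes in play: nothing to tilt
    else:
        odds_control = control_high / (n_control - control_high)
        # pilot: untilted case-style draws estimate the case placement
        # baseline; oversampled 3x so pilot noise is small next to the
        # estimator's own sampling noise
        pilot_high = pilot_n = 0
        for cnv_type, weight in (("loss", cfg.n_case_loss), ("gain", cfg.n_case_gain)):
            for _ in range(3 * weight):
                pilot_high += draw("case", cnv_type)[3]
                pilot_n += 1
        pilot_high = min(max(pilot_high, 1), pilot_n - 1)  # keep odds finite
        base_odds_case = pilot_high / (pilot_n - pilot_high)
        ratio = cfg.high_gene_or * odds_control / base_odds_case
        keep_high = min(1.0, ratio)
        keep_plain = min(1.0, 1.0 / ratio)

    case_rows = []
    for cnv_type in ("loss", "gain"):
        made = 0
        while made < jobs[("case", cnv_type)]:
            chrom, start, end, hh = draw("case", cnv_type)
            if rng.random() >= (keep_high if hh else keep_plain):
                continue
            case_rows.append((chrom, start, end, cnv_type, "case"))
            made += 1

    rows = []
    cls_names = list(cfg.classification_fracs)
    cls_p = np.array(list(cfg.classification_fracs.values()), dtype=float)
    cls_p /= cls_p.sum()
    cls_code = {"population": 1, "likely_benign": 2, "vous": 3, "pathogenic": 4}
    for chrom, start, end, cnv_type, cohort in case_rows + control_rows:
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        inh = "unknown"
        cls = None
        if cohort == "case":
            u = rng.random()
            acc = 0.0
            for k, f in cfg.inheritance_fracs.items():
                acc += f
                if u < acc:
                    inh = k
                    break
            cls = cls_code[cls_names[rng.choice(len(cls_names), p=cls_p)]]
        rows.append((chrom, start, end, cnv_type, cohort, sex, inh, cls))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "cnv_type", "cohort", "sex",
                 "inheritance", "classification"],
    )


def simulate_ortholog_table(
    n_genes: int = 8149,
    high_fraction: float = 0.12,
    class_ors: dict | None = None,
    base_rates: dict | None = None,
    enriched_terms: tuple = (
        "mortality_aging", "embryo", "nervous_system", "growth_size_body",
        "behavior_neurological", "cellular", "muscle",
    ),
    term_or: float = 1.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, set]:
    """Synthetic 1:1 ortholog table with configurable phenotype enrichment.

    Default mode: each of the 27 high-level terms is drawn per gene at a base
    rate, multiplied on the odds scale by ``term_or`` for high-scoring genes
    on the *enriched_terms*.

    Class mode (*class_ors* maps class names of the default class map to
    ORs): a latent per-class indicator is drawn with exactly the configured
    odds ratio between high-scoring and other genes (class base rates
    behavioral 0.35, nervous system 0.40, non-neurological 0.60), and a
    class that fires activates a random nonempty subset of its member terms,
    so the class-level 2x2 recovers the configured OR.

    Every gene carries at least one term. Returns
    (table, high_scoring_symbol_set).
    """
    rng = np.random.default_rng(seed)
    high = rng.random(n_genes) < high_fraction
    data = {t: np.zeros(n_genes, dtype=bool) for t in DEFAULT_PHENOTYPES}
    if class_ors is None:
        base = {t: 0.18 for t in DEFAULT_PHENOTYPES}
        base["normal"] = 0.25
        if base_rates:
            base.update(base_rates)
        for t in DEFAULT_PHENOTYPES:
            p0 = base[t]
            odds0 = p0 / (1 - p0)
            odds1 = odds0 * (term_or if t in enriched_terms else 1.0)
            p1 = odds1 / (1 + odds1)
            data[t] = np.where(
                high, rng.random(n_genes) < p1, rng.random(n_genes) < p0
            )
    else:
        class_base = {"behavioral": 0.35, "nervous_system": 0.40,
                      "non_neurological": 0.60}
        if base_rates:
            class_base.update(base_rates)
        for cls, orr in class_ors.items():
            p0 = class_base[cls]
            odds1 = p0 / (1 - p0) * orr
            p1 = odds1 / (1 + odds1)
            fired = np.where(high, rng.random(n_genes) < p1,
                             rng.random(n_genes) < p0)
            members = list(DEFAULT_CLASS_MAP[cls])
            forced = rng.integers(0, len(members), n_genes)
            for k, term in enumerate(members):
                hit = fired & ((rng.random(n_genes) < 0.5) | (forced == k))
                data[term] |= hit
    table = pd.DataFrame(data)
    # genes with no abnormal phenotype carry the class-free "normal" term so
    # every retained record has >=1 flag without distorting class odds
    none = ~table.any(axis=1)
    table.loc[none, "normal"] = True
    table.insert(0, "human_symbol", [f"G{i:05d}" for i in range(n_genes)])
    table.insert(1, "mouse_symbol", [f"g{i:05d}" for i in range(n_genes)])
    table.insert(2, "mgi_id", [f"MGI:{1000000 + i}" for i in range(n_genes)])
    high_set = set(table.loc[high, "human_symbol"])
    return table, high_set


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table2_counts", "table3_counts", "wbs_region", "region_22q11")

_FIXTURE_FILES = {
    "table2_counts": "table2_counts.json",
    "table3_counts": "table3_counts.json",
    "wbs_region": "wbs_region_synthetic.json",
    "region_22q11": "region_22q11_synthetic.json",
}

# sha256 of the packaged fixture files, verified on load
_FIXTURE_SHA256: dict[str, str] = {
    "table2_counts": "c7bdbbfe5546afa099347d2136890e75de95157f5220400b9aa133d9d3b13cae",
    "table3_counts": "a65987e4d0184d816156cafdbb128768017723b3cc80a338f71b68504c62e981",
    "wbs_region": "8fe3cc87b881144da0a6be600d8d7a12050cbd0c5f1a50a78df3c83c1516d3ad",
    "region_22q11": "4520d9ba3fb68654666f8fc6e29be309d5be739b3644bff9ac9663f27b0afd9e",
}


def _read_fixture(name: str) -> dict:
    fname = _FIXTURE_FILES[name]
    data = (resources.files("neuroscore") / "fixtures" / fname).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _FIXTURE_SHA256.get(name)
    if expected and digest != expected:
        raise ValueError(f"fixture {name} checksum mismatch")
    return json.loads(data)


def load_fixture(name: str):
    """Load a packaged count/region fixture by name.

    ``table2_counts`` -> DataFrame indexed by score level with columns
    total/cns/non_cns/no_phenotype/absent_from_omim;
    ``table3_counts`` -> {stratum: {cohort: Series indexed 5..0, NA}};
    ``wbs_region`` / ``region_22q11`` -> dict with a per-gene score table
    (synthetic stand-in scores; the counts are the meaningful content).
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}")
    raw = _read_fixture(name)
    if name == "table2_counts":
        df = pd.DataFrame(raw["levels"]).T
        df.index = df.index.astype(int)
        return df.sort_index()
    if name == "table3_counts":
        out = {}
        for stratum, cohorts in raw["counts"].items():
            out[stratum] = {
                cohort: pd.Series(
                    {(int(k) if k != "NA" else "NA"): v for k, v in counts.items()}
                ).reindex([5, 4, 3, 2, 1, 0, "NA"])
                for cohort, counts in cohorts.items()
            }
        return out
    genes = pd.DataFrame(raw["genes"])
    genes["score"] = genes["score"].astype("Int64")
    return {**{k: v for k, v in raw.items() if k != "genes"}, "genes": genes}
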