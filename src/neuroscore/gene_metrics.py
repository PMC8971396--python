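"""Harmonization of per-gene multi-omic inputs and binarization of evidence metrics.

Each candidate metric is reduced to a yes/no flag at the cutoff used by the
scoring model:

* ``gnomad_lof`` — gnomAD observed/expected loss-of-function upper bound
  strictly below 0.345 (0.35 with rounding from the thousandths place).
* ``ccr95`` / ``ccr99`` — at least one critically constrained coding region at
  or above the 95th / 99th percentile (inclusive).
* ``gtex`` — median brain expression across the 13 GTEx brain tissues at or
  above 10 TPM (inclusive).
* ``de_novo`` — at least 10 reported de novo variants.
* ``index`` — at least one exon flagged by the exon-indexing screen; the whole
  gene is promoted.

Missing inputs propagate to missing flags, so the scorer can emit NA for
genes absent from at least one source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Outcome",
    "GeneRecord",
    "MetricFlags",
    "HarmonizationReport",
    "FINAL_METRICS",
    "CANDIDATE_METRICS",
    "binarize_gnomad_lof",
    "binarize_ccr",
    "binarize_gtex",
    "binarize_denovo",
    "binarize_index",
    "MetricBinarizer",
    "harmonize",
]

#: The five flags retained by the final additive model, in scoring order.
FINAL_METRICS = ("de_novo", "index", "ccr99", "gtex", "gnomad_lof")

#: All nine candidate flags screened during model construction.
CANDIDATE_METRICS = FINAL_METRICS + ("ccr95", "gnomad_mis", "coe1", "coe2")


class Outcome(str, Enum):
    """Clinical-outcome label for a gene (OMIM-style annotation)."""

    CNS = "CNS"
    NON_CNS = "NON_CNS"
    NO_PHENOTYPE = "NO_PHENOTYPE"
    ABSENT = "ABSENT"


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return False


@dataclass
class GeneRecord:
    """One gene's identifiers, raw metric values and outcome label."""

    symbol: str
    ensembl_id: str | None = None
    aliases: tuple[str, ...] = ()
    oe_lof_upper: float | None = None
    oe_mis_upper: float | None = None
    ccr_max_percentile: float | None = None
    brain_tpm: Sequence[float] | float | None = None
    denovo_count: int | None = None
    index_flag: bool | None = None
    coe_p: float | None = None
    outcome: Outcome | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be nonempty")
        if not _is_missing(self.ccr_max_percentile) and not (
            0 <= self.ccr_max_percentile <= 100
        ):
            raise ValueError(
                f"{self.symbol}: ccr_max_percentile {self.ccr_max_percentile} "
                "outside [0, 100]"
            )
        if not _is_missing(self.denovo_count) and self.denovo_count < 0:
            raise ValueError(f"{self.symbol}: negative de novo count")


@dataclass(frozen=True)
class MetricFlags:
    """Binary evidence flags; ``None`` marks a metric missing at the source."""

    de_novo: bool | None = None
    index: bool | None = None
    ccr99: bool | None = None
    gtex: bool | None = None
    gnomad_lof: bool | None = None
    # audit flags for the rejected candidates
    ccr95: bool | None = None
    gnomad_mis: bool | None = None
    coe1: bool | None = None
    coe2: bool | None = None

    def final(self) -> tuple[bool | None, ...]:
        """The five flags of the final model, in scoring order."""
        return tuple(getattr(self, m) for m in FINAL_METRICS)


@dataclass
class HarmonizationReport:
    """Bookkeeping for a multi-source gene-table merge."""

    matched_by_id: int = 0
    matched_by_symbol: int = 0
    renamed: list[tuple[str, str]] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)
    na_scored: int = 0

    def to_dict(self) -> dict:
        return {
            "matched_by_id": self.matched_by_id,
            "matched_by_symbol": self.matched_by_symbol,
            "renamed": [list(pair) for pair in self.renamed],
            "unresolved": list(self.unresolved),
            "na_scored": self.na_scored,
        }


# ---------------------------------------------------------------------------
# binarizers
# ---------------------------------------------------------------------------

def binarize_gnomad_lof(oe_lof_upper: float | None, threshold: float = 0.345) -> bool | None:
    """Flag constrained genes: o/e LOF upper bound strictly below *threshold*."""
    if _is_missing(oe_lof_upper):
        return None
    if oe_lof_upper < 0:
        raise ValueError(f"o/e upper bound must be nonnegative, got {oe_lof_upper}")
    return bool(oe_lof_upper < threshold)


def binarize_ccr(ccr_max_percentile: float | None, level: int = 99) -> bool | None:
    """Flag genes whose top constrained-region percentile is at or above *level*."""
    if level not in (95, 99):
        raise ValueError(f"CCR level must be 95 or 99, got {level}")
    if _is_missing(ccr_max_percentile):
        return None
    if not 0 <= ccr_max_percentile <= 100:
        raise ValueError(f"percentile {ccr_max_percentile} outside [0, 100]")
    return bool(ccr_max_percentile >= level)


def binarize_gtex(brain_tpm, threshold: float = 10.0) -> bool | None:
    """Flag brain-expressed genes: median of the 13 per-tissue TPM medians >= threshold.

    Accepts either the per-tissue vector (reduced here by a median, with the
    even-length median taken as the mean of the two middle values) or a
    precomputed scalar median, which is compared directly.
    """
    if _is_missing(brain_tpm):
        return None
    if np.isscalar(brain_tpm):
        value = float(brain_tpm)
        if value < 0:
            raise ValueError("TPM must be nonnegative")
        return bool(value >= threshold)
    arr = np.asarray(brain_tpm, dtype=float)
    if arr.size == 0:
        raise ValueError("empty brain TPM vector")
    if np.isnan(arr).any():
        return None
    if (arr < 0).any():
        raise ValueError("TPM values must be nonnegative")
    return bool(float(np.median(arr)) >= threshold)


def binarize_denovo(denovo_count: int | None, threshold: int = 10) -> bool | None:
    """Flag genes with at least *threshold* reported de novo variants."""
    if _is_missing(denovo_count):
        return None
    if isinstance(denovo_count, float) and not float(denovo_count).is_integer():
        raise ValueError(f"de novo count must be an integer, got {denovo_count}")
    count = int(denovo_count)
    if count < 0:
        raise ValueError("de novo count must be nonnegative")
    return bool(count >= threshold)


def binarize_index(exon_flags: Iterable[bool]) -> bool:
    """Promote exon-level index hits to the gene: true iff any exon is flagged."""
    return any(bool(f) for f in exon_flags)


def dedupe_denovo_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate de novo variant reports.

    Variants identical on (subject, position, alternate allele) are counted
    once, a conservative rule for counts collated across overlapping studies.
    Expects columns ``subject``, ``position``, ``alt`` and optionally ``gene``.
    """
    keys = [c for c in ("subject", "position", "alt") if c in variants.columns]
    if not keys:
        raise ValueError("variant table lacks subject/position/alt columns")
    return variants.drop_duplicates(subset=keys)


class MetricBinarizer:
    """Transformer mapping raw per-gene metric columns to boolean evidence flags.

    scikit-learn compatible (stateless ``fit``; thresholds are parameters).
    ``transform`` takes a DataFrame with any of the columns ``oe_lof_upper``,
    ``oe_mis_upper``, ``ccr_max_percentile``, ``brain_tpm`` (scalar median) or
    ``brain_tpm_<i>`` tissue columns, ``denovo_count``, ``index_flag``,
    ``coe_p`` and returns a DataFrame of nullable-boolean flag columns.
    """

    def __init__(
        self,
        lof_threshold: float = 0.345,
        mis_threshold: float = 0.345,
        gtex_threshold: float = 10.0,
        denovo_threshold: int = 10,
        coe1_p: float = 0.01,
        coe2_p: float = 0.02,
    ):
        self.lof_threshold = lof_threshold
        self.mis_threshold = mis_threshold
        self.gtex_threshold = gtex_threshold
        self.denovo_threshold = denovo_threshold
        self.coe1_p = coe1_p
        self.coe2_p = coe2_p

    def get_params(self, deep: bool = True) -> dict:
        return {
            "lof_threshold": self.lof_threshold,
            "mis_threshold": self.mis_threshold,
            "gtex_threshold": self.gtex_threshold,
            "denovo_threshold": self.denovo_threshold,
            "coe1_p": self.coe1_p,
            "coe2_p": self.coe2_p,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "MetricBinarizer":
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=X.index)

        def _lt(col, thr):
            s = pd.to_numeric(X[col], errors="coerce")
            if (s.dropna() < 0).any():
                raise ValueError(f"negative values in {col}")
            return (s < thr).astype("boolean").mask(s.isna())

        def _ge(s, thr):
            s = pd.to_numeric(s, errors="coerce")
            return (s >= thr).astype("boolean").mask(s.isna())

        if "oe_lof_upper" in X:
            out["gnomad_lof"] = _lt("oe_lof_upper", self.lof_threshold)
        if "oe_mis_upper" in X:
            out["gnomad_mis"] = _lt("oe_mis_upper", self.mis_threshold)
        if "ccr_max_percentile" in X:
            pct = pd.to_numeric(X["ccr_max_percentile"], errors="coerce")
            valid = pct.dropna()
            if ((valid < 0) | (valid > 100)).any():
                raise ValueError("ccr_max_percentile outside [0, 100]")
            out["ccr95"] = _ge(pct, 95)
            out["ccr99"] = _ge(pct, 99)
        tissue_cols = [c for c in X.columns if c.startswith("brain_tpm_")]
        if tissue_cols:
            med = X[tissue_cols].apply(pd.to_numeric, errors="coerce").median(axis=1)
            med = med.mask(X[tissue_cols].isna().any(axis=1))
            out["gtex"] = _ge(med, self.gtex_threshold)
        elif "brain_tpm" in X:
            out["gtex"] = _ge(X["brain_tpm"], self.gtex_threshold)
        if "denovo_count" in X:
            out["de_novo"] = _ge(X["denovo_count"], self.denovo_threshold)
        if "index_flag" in X:
            s = X["index_flag"]
            out["index"] = s.astype("boolean")
        if "coe_p" in X:
            p = pd.to_numeric(X["coe_p"], errors="coerce")
            out["coe1"] = (p <= self.coe1_p).astype("boolean").mask(p.isna())
            out["coe2"] = (p <= self.coe2_p).astype("boolean").mask(p.isna())
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def flags_from_record(record: GeneRecord, binarizer: MetricBinarizer | None = None) -> MetricFlags:
    """Binarize one gene's raw metric values into a :class:`MetricFlags`."""
    b = binarizer or MetricBinarizer()
    return MetricFlags(
        de_novo=binarize_denovo(record.denovo_count, b.denovo_threshold),
        index=None if _is_missing(record.index_flag) else bool(record.index_flag),
        ccr99=binarize_ccr(record.ccr_max_percentile, 99),
        ccr95=binarize_ccr(record.ccr_max_percentile, 95),
        gtex=binarize_gtex(record.brain_tpm, b.gtex_threshold),
        gnomad_lof=binarize_gnomad_lof(record.oe_lof_upper, b.lof_threshold),
        gnomad_mis=binarize_gnomad_lof(record.oe_mis_upper, b.mis_threshold)
        if not _is_missing(record.oe_mis_upper)
        else None,
        coe1=None if _is_missing(record.coe_p) else bool(record.coe_p <= b.coe1_p),
        coe2=None if _is_missing(record.coe_p) else bool(record.coe_p <= b.coe2_p),
    )


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

BIOTYPE_EXCLUDED = {
    "non_coding",
    "lncRNA",
    "ncRNA",
    "rRNA",
    "tRNA",
    "snoRNA",
    "miRNA",
    "mitochondrial",
    "Mt_tRNA",
    "Mt_rRNA",
    "pseudogene",
    "processed_pseudogene",
    "unprocessed_pseudogene",
}


def harmonize(
    tables: Sequence[pd.DataFrame],
    alias_map: Mapping[str, str] | None = None,
    require_all_sources: bool = True,
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Merge per-source gene tables into one row per gene.

    Each table must carry a ``symbol`` column and may carry ``ensembl_id``
    plus any raw metric columns. Match priority is stable identifier, then
    current symbol, then the alias map (old symbol -> current symbol). Two
    sources assigning different identifiers to one symbol make that symbol
    unresolved rather than silently merged. Rows whose ``biotype`` is a
    non-coding/pseudogene class are excluded up front.

    Returns the merged table (indexed 0..n-1, with ``symbol``, ``ensembl_id``
    and the union of metric columns; ``incomplete`` marks genes absent from at
    least one source, which the scorer turns into NA when
    *require_all_sources*) and a :class:`HarmonizationReport`.
    """
    alias_map = dict(alias_map or {})
    report = HarmonizationReport()

    # first pass: symbol -> identifier consensus, detect conflicts
    symbol_to_id: dict[str, set[str]] = {}
    id_symbols: dict[str, list[str]] = {}
    for table in tables:
        if "symbol" not in table.columns:
            raise ValueError("every source table needs a 'symbol' column")
        if "ensembl_id" in table.columns:
            for sym, eid in zip(table["symbol"], table["ensembl_id"]):
                if _is_missing(eid) or eid == "":
                    continue
                symbol_to_id.setdefault(sym, set()).add(eid)
                id_symbols.setdefault(eid, []).append(sym)
    conflicted = {s for s, ids in symbol_to_id.items() if len(ids) > 1}
    id_of = {s: next(iter(ids)) for s, ids in symbol_to_id.items() if len(ids) == 1}
    # one canonical symbol per identifier: the alias-map target when one of the
    # colliding symbols is an alias of another, else the first symbol seen
    canon_of_id: dict[str, str] = {}
    for eid, syms in id_symbols.items():
        syms = [s for s in dict.fromkeys(syms) if s not in conflicted]
        if not syms:
            continue
        canonical = syms[0]
        for s in syms:
            target = alias_map.get(s)
            if target in syms:
                canonical = target
                break
        canon_of_id[eid] = canonical
    # a current symbol reachable through an alias inherits the alias target's id
    canonical_of_alias = {
        old: new for old, new in alias_map.items() if old not in id_of
    }

    merged: dict[str, dict] = {}
    seen_sources: dict[str, set[int]] = {}
    for source_idx, table in enumerate(tables):
        if "biotype" in table.columns:
            table = table[~table["biotype"].isin(BIOTYPE_EXCLUDED)]
        for _, row in table.iterrows():
            sym = row["symbol"]
            eid = row.get("ensembl_id")
            if _is_missing(eid) or eid == "":
                eid = None
            if sym in conflicted:
                if sym not in report.unresolved:
                    report.unresolved.append(sym)
                continue
            canonical = sym
            if eid is not None:
                # identifier match: adopt the canonical symbol for this id
                canonical = canon_of_id.get(eid, sym)
                if canonical != sym:
                    report.renamed.append((sym, canonical))
                report.matched_by_id += 1
            elif sym in id_of or sym in merged:
                report.matched_by_symbol += 1
            elif sym in canonical_of_alias:
                canonical = canonical_of_alias[sym]
                report.renamed.append((sym, canonical))
                report.matched_by_symbol += 1
            key = canonical
            entry = merged.setdefault(key, {"symbol": canonical, "ensembl_id": None})
            if eid is not None and entry["ensembl_id"] is None:
                entry["ensembl_id"] = eid
            for col, value in row.items():
                if col in ("symbol", "ensembl_id", "biotype", "incomplete"):
                    continue
                if col not in entry or _is_missing(entry[col]):
                    entry[col] = value
            if bool(row.get("incomplete", False)):
                entry["_carried_incomplete"] = True
            seen_sources.setdefault(key, set()).add(source_idx)

    out = pd.DataFrame(list(merged.values()))
    if not out.empty:
        out = out.sort_values("symbol", kind="mergesort").reset_index(drop=True)
        n_sources = len(tables)
        carried = (
            out.pop("_carried_incomplete").astype("boolean").fillna(False).astype(bool)
            if "_carried_incomplete" in out.columns
            else pd.Series(False, index=out.index)
        )
        fresh = pd.Series(
            [
                len(seen_sources[s]) < n_sources if require_all_sources else False
                for s in out["symbol"]
            ],
            index=out.index,
        )
        out["incomplete"] = carried | fresh
        report.na_scored = int(out["incomplete"].sum())
    else:
        out = pd.DataFrame(columns=["symbol", "ensembl_id", "incomplete"])
    # dedupe renamed pairs, preserve order
    report.renamed = list(dict.fromkeys(report.renamed))
    return out, report
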