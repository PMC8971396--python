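"""Human-mouse ortholog matching and high-level phenotype enrichment.

Raw pairing tables are many-to-many; analysis keeps only clean 1:1 human-mouse
pairs that carry at least one high-level phenotype annotation (a missing
knockout phenotype record says nothing about what variants of the gene can
cause). High-scoring-gene enrichment is then tested per phenotype term with
chi-squared (Bonferroni across the 27 terms) and summarized per phenotype
class (behavioral, nervous system, non-neurological) as odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc_stats import AssociationResult, chi2_test, odds_ratio_2x2

__all__ = [
    "DEFAULT_PHENOTYPES",
    "DEFAULT_CLASS_MAP",
    "OrthologRecord",
    "filter_orthologs",
    "phenotype_enrichment",
    "phenotype_class_or",
]

#: Frozen vocabulary of high-level mouse phenotype terms (MGI-style). The
#: vocabulary is configurable; this is the 27-term set shipped for tests.
DEFAULT_PHENOTYPES: tuple[str, ...] = (
    "adipose_tissue",
    "behavior_neurological",
    "cardiovascular",
    "cellular",
    "craniofacial",
    "digestive_alimentary",
    "embryo",
    "endocrine_exocrine",
    "growth_size_body",
    "hearing_vestibular",
    "hematopoietic",
    "homeostasis_metabolism",
    "immune",
    "integument",
    "limbs_digits_tail",
    "liver_biliary",
    "mortality_aging",
    "muscle",
    "nervous_system",
    "normal",
    "pigmentation",
    "renal_urinary",
    "reproductive",
    "respiratory",
    "skeleton",
    "taste_olfaction",
    "vision_eye",
)

#: Phenotype-class groupings used for the class-level odds ratios.
DEFAULT_CLASS_MAP: dict[str, tuple[str, ...]] = {
    "behavioral": ("behavior_neurological",),
    "nervous_system": ("nervous_system",),
    "non_neurological": tuple(
        t
        for t in DEFAULT_PHENOTYPES
        if t not in ("behavior_neurological", "nervous_system", "normal")
    ),
}


@dataclass(frozen=True)
class OrthologRecord:
    """A 1:1 human-mouse gene pairing with high-level phenotype flags."""

    human_symbol: str
    mouse_symbol: str
    mgi_id: str
    phenotype_flags: tuple[bool, ...]

    @property
    def n_phenotypes(self) -> int:
        return sum(self.phenotype_flags)


def filter_orthologs(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame | None = None,
    phenotype_columns: Sequence[str] = DEFAULT_PHENOTYPES,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Reduce a raw pairing table to analyzable 1:1 pairs with phenotype data.

    *pairs* needs ``human_symbol`` and ``mouse_symbol`` (plus ``mgi_id`` and
    optionally the phenotype flag columns; alternatively *phenotypes* is a
    separate per-mouse-gene flag table merged on ``mouse_symbol``).

    Exclusion rules, tallied by reason:

    * ``multi_human`` — a mouse gene pairing with two or more human genes
      (all its links removed);
    * ``multi_mouse`` — several mouse genes pairing with one human gene;
    * ``no_phenotype`` — retained pairs with no phenotype flag set (or no
      phenotype record at all).
    """
    df = pairs.copy()
    if phenotypes is not None:
        df = df.merge(phenotypes, on="mouse_symbol", how="left")
    tally = {"multi_human": 0, "multi_mouse": 0, "no_phenotype": 0}

    multi_h = df.groupby("mouse_symbol")["human_symbol"].transform("nunique") > 1
    tally["multi_human"] = int(multi_h.sum())
    df = df[~multi_h]

    multi_m = df.groupby("human_symbol")["mouse_symbol"].transform("nunique") > 1
    tally["multi_mouse"] = int(multi_m.sum())
    df = df[~multi_m]

    flag_cols = [c for c in phenotype_columns if c in df.columns]
    if not flag_cols:
        raise ValueError("no phenotype flag columns found")
    flags = df[flag_cols].astype("boolean").fillna(False).astype(bool)
    has_pheno = flags.any(axis=1)
    tally["no_phenotype"] = int((~has_pheno).sum())
    out = df[has_pheno].copy()
    out[flag_cols] = flags[has_pheno]
    out["n_phenotypes"] = flags[has_pheno].sum(axis=1)
    return out.reset_index(drop=True), tally


def phenotype_enrichment(
    records: pd.DataFrame,
    high_scoring: set[str],
    phenotype_columns: Sequence[str] = DEFAULT_PHENOTYPES,
    alpha: float = 0.05 / 27,
) -> pd.DataFrame:
    """Chi-squared enrichment of high-scoring genes in each phenotype term.

    One 2x2 test per term of high-scoring membership x phenotype flag,
    declared significant at the Bonferroni-corrected *alpha* (0.05/27 by
    default). Degenerate terms (no variation in either margin) are skipped.
    """
    high = records["human_symbol"].isin(high_scoring)
    rows = []
    for term in phenotype_columns:
        if term not in records.columns:
            continue
        flag = records[term].astype(bool)
        if flag.nunique() < 2 or high.nunique() < 2:
            rows.append({"phenotype": term, "or": None, "ci_low": None,
                         "ci_high": None, "statistic": None, "p": None,
                         "significant": False, "note": "degenerate"})
            continue
        table = pd.crosstab(high, flag).reindex(
            index=[True, False], columns=[True, False], fill_value=0
        ).values
        chi = chi2_test(table)
        orr = odds_ratio_2x2(table)
        rows.append(
            {"phenotype": term, "or": orr.or_estimate, "ci_low": orr.ci_low,
             "ci_high": orr.ci_high, "statistic": chi.statistic, "p": chi.p,
             "significant": bool(chi.p < alpha), "note": ""}
        )
    return pd.DataFrame(rows)


def phenotype_class_or(
    records: pd.DataFrame,
    high_scoring: set[str],
    class_map: Mapping[str, Sequence[str]] = DEFAULT_CLASS_MAP,
    ci_level: float = 0.95,
) -> dict[str, AssociationResult]:
    """Odds ratio of high-scoring membership per phenotype class.

    A gene carries a class flag when any of the class's phenotype terms is
    set; each class yields a 2x2 odds ratio (high-scoring x class flag).
    """
    high = records["human_symbol"].isin(high_scoring)
    out: dict[str, AssociationResult] = {}
    for cls, terms in class_map.items():
        cols = [t for t in terms if t in records.columns]
        if not cols:
            raise ValueError(f"class {cls!r} has no phenotype columns present")
        flag = records[cols].astype(bool).any(axis=1)
        table = pd.crosstab(high, flag).reindex(
            index=[True, False], columns=[True, False], fill_value=0
        ).values
        out[cls] = odds_ratio_2x2(table, ci_level)
    return out
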