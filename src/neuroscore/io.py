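"""Readers, writers and run configuration.

CNV coordinates are stored 0-based half-open internally. BED input is taken
as-is; TSV input declared 1-based inclusive is converted on load. Reports
print 1-based inclusive coordinates. Every writer embeds a provenance block
(configuration, seed, package version) so a run can be reproduced from its
outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel

from . import __version__

__all__ = [
    "RunConfig",
    "ReadError",
    "read_cnv_table",
    "read_gene_metrics",
    "read_exon_bed",
    "write_report",
    "read_report",
]

_CLASSIFICATION_ALIASES = {
    "1": 1, "2": 2, "3": 3, "4": 4,
    "population": 1, "likely_benign": 2, "vous": 3, "pathogenic": 4,
    "likely_pathogenic": 4, "": None, "unknown": None,
}


class RunConfig(BaseModel):
    """Thresholds and schedules for a reproducible analysis run."""

    lof_threshold: float = 0.345
    mis_threshold: float = 0.345
    gtex_threshold: float = 10.0
    denovo_threshold: int = 10
    ccr_level: int = 99
    screen_alpha: float = 0.05
    model_alpha: float = 0.05
    vif_limit: float = 5.0
    cohort_bonferroni_tests: int = 10
    level_bonferroni_alpha: float = 0.004
    fisher_rule: str = "cell_le_5"
    overlap_mode: str = "exon"
    coordinate_dialect: str = "bed"
    lenient_scoring: bool = False
    seed: int = 0


@dataclass
class ReadError:
    line: int
    message: str


def read_cnv_table(path, dialect: str = "bed") -> tuple[pd.DataFrame, list[ReadError]]:
    """Read CNV calls from a BED4+ or TSV file.

    ``dialect='bed'`` keeps coordinates 0-based half-open;
    ``dialect='tsv_one_based'`` converts 1-based inclusive starts.
    Expected columns (header optional for BED): chrom, start, end, cnv_type
    and optionally cohort, sex, inheritance, classification. Malformed lines
    are collected with their line numbers instead of aborting the load.
    """
    if dialect not in ("bed", "tsv_one_based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    errors: list[ReadError] = []
    rows = []
    columns = ["chrom", "start", "end", "cnv_type", "cohort", "sex",
               "inheritance", "classification"]
    with open(path) as fh:
        lines = fh.readlines()
    header_offset = 0
    if lines and lines[0].lower().lstrip().startswith(("chrom", "#chrom", "track")):
        header_offset = 1
    for lineno, line in enumerate(lines[header_offset:], start=header_offset + 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            errors.append(ReadError(lineno, "fewer than 4 columns"))
            continue
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            errors.append(ReadError(lineno, "non-integer coordinates"))
            continue
        if dialect == "tsv_one_based":
            start -= 1
        if end <= start:
            errors.append(ReadError(lineno, "end <= start"))
            continue
        cnv_type = parts[3].lower()
        if cnv_type not in ("loss", "gain"):
            errors.append(ReadError(lineno, f"unknown CNV type {parts[3]!r}"))
            continue
        extra = parts[4:8] + [""] * (4 - len(parts[4:8]))
        cls_raw = extra[3].strip().lower()
        if cls_raw not in _CLASSIFICATION_ALIASES:
            errors.append(ReadError(lineno, f"unknown classification {extra[3]!r}"))
            continue
        rows.append(
            [parts[0], start, end, cnv_type,
             extra[0] or "case", extra[1] or "unknown", extra[2] or "unknown",
             _CLASSIFICATION_ALIASES[cls_raw]]
        )
    df = pd.DataFrame(rows, columns=columns)
    if df.empty and not rows:
        import warnings

        warnings.warn(f"{path}: no CNV records read", stacklevel=2)
    return df, errors


def read_gene_metrics(path) -> pd.DataFrame:
    """Read a per-gene metric TSV (one row per gene, ``symbol`` required)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "symbol" not in df.columns:
        raise ValueError("gene metric table needs a 'symbol' column")
    return df


def read_exon_bed(path) -> pd.DataFrame:
    """Read exon models from a BED file.

    Accepts 4-column exon BED (chrom, start, end, gene) or 12-column BED
    whose blocks are expanded into exons with the record name as the gene.
    """
    first = pd.read_csv(path, sep="\t", header=None, nrows=1, comment="#")
    ncols = first.shape[1]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if ncols >= 12:
        rows = []
        for _, r in df.iterrows():
            chrom, start, name = r[0], int(r[1]), r[3]
            sizes = [int(x) for x in str(r[10]).rstrip(",").split(",")]
            starts = [int(x) for x in str(r[11]).rstrip(",").split(",")]
            for bs, bl in zip(starts, sizes):
                rows.append((chrom, start + bs, start + bs + bl, name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    if ncols < 4:
        raise ValueError("exon BED needs at least 4 columns")
    out = df.iloc[:, :4].copy()
    out.columns = ["chrom", "start", "end", "gene"]
    return out


def _provenance(config: RunConfig | dict | None, seed: int | None) -> dict:
    cfg = config.model_dump() if isinstance(config, RunConfig) else dict(config or {})
    return {"package": "neuroscore", "version": __version__, "seed": seed, "config": cfg}


def write_report(
    results,
    path,
    fmt: str = "tsv",
    config: RunConfig | dict | None = None,
    seed: int | None = None,
    float_precision: int = 6,
) -> Path:
    """Write an analysis result deterministically with a provenance block.

    DataFrames go to TSV (provenance as ``#`` comment lines, fixed float
    format, stable column order) or JSON (records plus a ``_provenance``
    key); dicts and dataclass-style results go to JSON.
    """
    path = Path(path)
    prov = _provenance(config, seed)
    if fmt == "tsv":
        if not isinstance(results, pd.DataFrame):
            raise ValueError("tsv format expects a DataFrame")
        with open(path, "w") as fh:
            fh.write(f"# provenance: {json.dumps(prov, sort_keys=True)}\n")
            results.to_csv(fh, sep="\t", index=False,
                           float_format=f"%.{float_precision}g")
    elif fmt == "json":
        if isinstance(results, pd.DataFrame):
            payload = results.to_dict(orient="records")
        elif hasattr(results, "to_dict"):
            payload = results.to_dict()
        else:
            payload = results
        with open(path, "w") as fh:
            json.dump({"results": payload, "_provenance": prov}, fh, indent=2,
                      sort_keys=True, default=str)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_report(path):
    """Round-trip reader for :func:`write_report` output."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            prov = json.loads(first.split(":", 1)[1])
            df = pd.read_csv(fh, sep="\t")
            return df, prov
    payload = json.loads(path.read_text())
    if isinstance(payload, dict) and "_provenance" in payload:
        return payload["results"], payload["_provenance"]
    return payload, None
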