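"""File I/O and report serialisation.

Ratings travel as UTF-8 CSV with columns ``case_id, drug_a, drug_b,
rater, category`` (header required). Cross-tables read/write as labelled
CSV matrices. Result objects serialise to JSON with full float precision;
the text rendering of a cross-table mirrors the conventional layout with
a Total row and column.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import (
    BlandAltmanResult,
    CrossTable,
    KappaResult,
    ProportionCI,
    round_half_up,
)
from .scales import RatingRecord, RatingScale, ScaleError
from .study import ComparisonResult, ValidationReport

RATINGS_COLUMNS = ("case_id", "drug_a", "drug_b", "rater", "category")


class RatingsFormatError(ValueError):
    pass


def read_ratings(
    path: str | Path,
    scales: Mapping[str, RatingScale] | None = None,
) -> list[RatingRecord]:
    """Read rating records from CSV, validating categories where possible.

    ``scales`` maps rater names to their scales; categories of raters with
    a known scale are validated and canonicalized, and errors carry the
    offending CSV row number (header = line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records: list[RatingRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header occupies line 1
        category = row.category
        if scales and row.rater in scales:
            try:
                category = scales[row.rater].canonicalize(category)
            except ScaleError as exc:
                raise RatingsFormatError(f"{path}, line {line}: {exc}") from exc
        records.append(
            RatingRecord(row.case_id, row.drug_a, row.drug_b, row.rater, category)
        )
    return records


def write_ratings(records: Sequence[RatingRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records], columns=RATINGS_COLUMNS).to_csv(
        path, index=False
    )


def read_cross_table(
    path: str | Path, row_rater: str = "A", col_rater: str = "B"
) -> CrossTable:
    """Read a labelled CSV count matrix (first column = row labels)."""
    df = pd.read_csv(path, index_col=0)
    return CrossTable(
        df.to_numpy(dtype=np.int64),
        row_rater,
        col_rater,
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
    )


def write_cross_table(table: CrossTable, path: str | Path) -> None:
    table.to_frame().to_csv(path)


def render_cross_table_text(table: CrossTable) -> str:
    """Plain-text cross-table with marginal totals."""
    frame = table.to_frame()
    frame["Total"] = frame.sum(axis=1)
    frame.loc["Total"] = frame.sum(axis=0)
    frame.index.name = table.row_rater
    frame.columns.name = table.col_rater
    return frame.to_string()


# ---------------------------------------------------------------------------
# result serialisation


def kappa_to_dict(result: KappaResult) -> dict:
    return {
        "kappa": result.kappa,
        "po": result.po,
        "pe": result.pe,
        "scheme": result.scheme,
        "se": result.se,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "band": result.band,
        "n": result.n,
        "degenerate": result.degenerate,
    }


def bland_altman_to_dict(result: BlandAltmanResult) -> dict:
    return dataclasses.asdict(result)


def proportion_to_dict(result: ProportionCI) -> dict:
    d = dataclasses.asdict(result)
    pct, low, high = result.as_percent()
    d["percent"] = {"estimate": pct, "ci_low": low, "ci_high": high}
    return d


def comparison_to_dict(result: ComparisonResult) -> dict:
    return {
        "label": result.label,
        "n": result.table.n,
        "cross_table": {
            "rows": list(result.table.row_labels),
            "columns": list(result.table.col_labels),
            "counts": result.table.counts.tolist(),
        },
        "kappa": kappa_to_dict(result.kappa),
        "weighted_kappa": kappa_to_dict(result.kappa_weighted),
        "wilson": proportion_to_dict(result.concordance),
        "bland_altman": bland_altman_to_dict(result.bland_altman),
        "post_exclusion": {
            "excluded_n": result.excluded_n,
            "n": result.table_post.n,
            "kappa": kappa_to_dict(result.kappa_post),
            "bland_altman": bland_altman_to_dict(result.bland_altman_post),
            "residual_disagreements": proportion_to_dict(result.residual_disagreements),
        },
    }


def report_to_dict(report: ValidationReport) -> dict:
    return {
        "comparisons": {
            "dm_vs_pharmacologist": comparison_to_dict(report.dm_vs_pharm),
            "dm_vs_mmx": comparison_to_dict(report.dm_vs_mmx),
        },
        "expectations": [
            {
                "name": e.name,
                "reported": _jsonable(e.reported),
                "computed": _jsonable(e.computed),
                "ok": e.ok,
            }
            for e in report.expectations
        ],
        "all_ok": report.all_ok,
        "not_reproducible": list(report.not_reproducible),
    }


def _jsonable(value: object) -> object:
    if isinstance(value, tuple):
        return list(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def write_report(report: ValidationReport, fmt: str = "json") -> str:
    """Serialise a validation report as JSON or a human-readable summary."""
    if fmt == "json":
        return json.dumps(report_to_dict(report), indent=2)
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")
    lines: list[str] = []
    for comp in (report.dm_vs_pharm, report.dm_vs_mmx):
        lines.append(f"== {comp.label} (n = {comp.table.n}) ==")
        lines.append(render_cross_table_text(comp.table))
        pct, lo, hi = comp.concordance.as_percent()
        lines += [
            f"kappa                 {comp.kappa.kappa:.3f} ({comp.kappa.band})",
            f"weighted kappa (lin)  {comp.kappa_weighted.kappa:.3f} ({comp.kappa_weighted.band})",
            f"concordance           {comp.concordance.x}/{comp.concordance.n} "
            f"= {pct}% (95% CI [{lo}, {hi}])",
            f"Bland-Altman          mean {round_half_up(comp.bland_altman.mean, 2)}, "
            f"limits [{round_half_up(comp.bland_altman.loa_low, 2)}, "
            f"{round_half_up(comp.bland_altman.loa_high, 2)}]",
            f"post-exclusion        n {comp.bland_altman_post.n}, "
            f"mean {round_half_up(comp.bland_altman_post.mean, 2)}, "
            f"limits [{round_half_up(comp.bland_altman_post.loa_low, 2)}, "
            f"{round_half_up(comp.bland_altman_post.loa_high, 2)}]",
            f"residual disagreement {comp.residual_disagreements.x}/{comp.residual_disagreements.n}",
            "",
        ]
    lines.append("checks against the reported study values:")
    for e in report.expectations:
        status = "ok      " if e.ok else "MISMATCH"
        lines.append(f"  [{status}] {e.name}: reported {e.reported} / computed {e.computed}")
    lines.append("")
    lines.append("not reproducible from published data:")
    for item in report.not_reproducible:
        lines.append(f"  - {item}")
    return "\n".join(lines) + "\n"
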