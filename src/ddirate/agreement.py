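"""Inter-rater agreement statistics for ordinal severity ratings.

Two raters assign each of *n* cases to one of *k* ordered categories coded
1..k; their joint distribution is a k x k cross-table. This module computes
the statistics used to validate one rating system against another:

* ordinary (unweighted) and weighted Cohen's kappa, with the asymptotic
  large-sample standard error of Fleiss, Cohen & Everitt;
* Bland-Altman analysis of the per-case difference of numeric codes
  (mean difference and 95% limits of agreement, mean +/- 1.96 SD) —
  positive differences mean the row rater assigns higher severity;
* Wilson score confidence intervals for proportions (concordance rate,
  disagreement rates);
* cell masking, used to exclude systematic, structurally explained
  disagreements (and missing-information cells) before re-analysis.

Linear disagreement weights ``1 - |i-j|/(k-1)`` are the default weighting
scheme: adjacent-category disagreements are discounted less than
disagreements of two or more categories. Quadratic weights are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .scales import RatingRecord, RatingScale

Z95 = 1.96

WeightScheme = Literal["none", "linear", "quadratic"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention used for reported
    values (e.g. a mean difference of exactly 0.125 prints as 0.13)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))

#: Interpretation bands for kappa (Altman's convention); values below the
#: first cut-point indicate agreement no better than chance.
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.81, "perfect agreement"),
    (0.61, "substantial agreement"),
    (0.41, "moderate agreement"),
    (0.21, "fair agreement"),
    (0.01, "slight agreement"),
    (0.0, "poor agreement"),
)


def interpret_kappa(kappa: float) -> str:
    if kappa < 0:
        return "less than chance"
    for cut, band in KAPPA_BANDS:
        if kappa >= cut:
            return band
    return "poor agreement"


class AgreementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cross-tables and masks


@dataclass(frozen=True)
class CrossTable:
    """k x k contingency counts of two raters over the same cases.

    Rows index the first rater's categories (code order), columns the
    second's. ``row_labels``/``col_labels`` carry the category labels of
    the two (aligned) scales.
    """

    counts: np.ndarray
    row_rater: str
    col_rater: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise AgreementError("cross-table must be square")
        if (counts < 0).any():
            raise AgreementError("cross-table counts must be non-negative")
        if counts.shape[0] != len(self.row_labels) or counts.shape[1] != len(self.col_labels):
            raise AgreementError("label count does not match table dimension")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal(self) -> int:
        return int(np.trace(self.counts))

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.row_labels), columns=list(self.col_labels)
        )

    def expand_differences(self) -> np.ndarray:
        """Per-case differences (row code - col code) expanded from counts."""
        diffs: list[np.ndarray] = []
        for i in range(self.k):
            for j in range(self.k):
                c = self.counts[i, j]
                if c:
                    diffs.append(np.full(c, i - j, dtype=float))
        return np.concatenate(diffs) if diffs else np.empty(0)


@dataclass(frozen=True)
class CellMask:
    """Cross-table cells to exclude, addressed by (row label, col label)."""

    cells: frozenset[tuple[str, str]]
    reason: str = ""

    def __init__(self, cells: Iterable[tuple[str, str]], reason: str = "") -> None:
        object.__setattr__(self, "cells", frozenset((str(r), str(c)) for r, c in cells))
        object.__setattr__(self, "reason", reason)

    def indices(self, table: CrossTable) -> list[tuple[int, int]]:
        out = []
        for row, col in sorted(self.cells):
            if row not in table.row_labels or col not in table.col_labels:
                raise AgreementError(
                    f"mask cell ({row!r}, {col!r}) outside table bounds"
                )
            out.append((table.row_labels.index(row), table.col_labels.index(col)))
        return out

    def masked_count(self, table: CrossTable) -> int:
        return int(sum(table.counts[i, j] for i, j in self.indices(table)))


def apply_mask(table: CrossTable, mask: CellMask) -> CrossTable:
    """Zero the masked cells, reducing n accordingly (original unchanged)."""
    counts = table.counts.copy()
    for i, j in mask.indices(table):
        counts[i, j] = 0
    if counts.sum() == 0:
        raise AgreementError("table is empty after masking")
    return CrossTable(
        counts, table.row_rater, table.col_rater, table.row_labels, table.col_labels
    )


def build_cross_table(
    records_a: Sequence[RatingRecord],
    records_b: Sequence[RatingRecord],
    scale_a: RatingScale,
    scale_b: RatingScale,
) -> CrossTable:
    """Cross-tabulate two raters' records over their shared cases.

    Both collections must cover exactly the same case ids, one rating per
    case per rater; cell (i, j) counts cases placed in category i by rater
    A and category j by rater B.
    """

    def index(records: Sequence[RatingRecord], scale: RatingScale, who: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in records:
            if rec.case_id in out:
                raise AgreementError(
                    f"case {rec.case_id!r} rated more than once by {who}"
                )
            code, _ = scale.encode(rec.category)
            out[rec.case_id] = code
        return out

    a = index(records_a, scale_a, "rater A")
    b = index(records_b, scale_b, "rater B")
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:5]
        only_b = sorted(set(b) - set(a))[:5]
        raise AgreementError(
            f"case ids differ between raters (only A: {only_a}, only B: {only_b})"
        )
    k = len(scale_a)
    if len(scale_b) != k:
        raise AgreementError("raters use scales of different arity")
    counts = np.zeros((k, k), dtype=np.int64)
    for case_id, code_a in a.items():
        counts[code_a - 1, b[case_id] - 1] += 1
    rater_a = records_a[0].rater if records_a else scale_a.name
    rater_b = records_b[0].rater if records_b else scale_b.name
    return CrossTable(counts, rater_a, rater_b, scale_a.categories, scale_b.categories)


# ---------------------------------------------------------------------------
# Cohen's kappa


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected agreement kappa = (Po - Pe) / (1 - Pe).

    ``po``/``pe`` are the (weight-averaged) observed and expected
    agreement proportions; for the unweighted statistic the weights are
    the identity matrix. ``se`` is the asymptotic large-sample standard
    error; ``ci_low``/``ci_high`` the corresponding kappa +/- 1.96 SE
    interval.
    """

    kappa: float
    po: float
    pe: float
    scheme: WeightScheme
    weights: np.ndarray
    se: float
    ci_low: float
    ci_high: float
    band: str
    n: int
    degenerate: bool = False
    small_sample: bool = False


def weight_matrix(k: int, scheme: WeightScheme) -> np.ndarray:
    """Agreement weights: 1 on the diagonal, decaying with |i - j|."""
    i, j = np.indices((k, k))
    if scheme == "none":
        return (i == j).astype(float)
    d = np.abs(i - j) / (k - 1)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise AgreementError(f"unknown weight scheme {scheme!r}")


def _kappa(table: CrossTable, scheme: WeightScheme) -> KappaResult:
    n = table.n
    if n < 1:
        raise AgreementError("empty cross-table")
    k = table.k
    w = weight_matrix(k, scheme)
    p = table.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    if (row > 0).sum() < 2 and (col > 0).sum() < 2:
        # both raters use a single category: Pe = 1, kappa undefined
        return KappaResult(
            kappa=float("nan"), po=float((w * p).sum()), pe=1.0, scheme=scheme,
            weights=w, se=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            band="undefined (degenerate table)", n=n, degenerate=True,
        )
    po = float((w * p).sum())
    pe = float((w * np.outer(row, col)).sum())
    if np.isclose(pe, 1.0):
        return KappaResult(
            kappa=float("nan"), po=po, pe=pe, scheme=scheme, weights=w,
            se=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            band="undefined (degenerate table)", n=n, degenerate=True,
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-Cohen-Everitt asymptotic variance of weighted kappa
    wbar_row = w @ col          # E_j[w_ij] over the column marginal
    wbar_col = row @ w          # E_i[w_ij] over the row marginal
    cross = wbar_row[:, None] + wbar_col[None, :]
    term = (w - cross * (1.0 - kappa)) ** 2
    var = (float((p * term).sum()) - (kappa - pe * (1.0 - kappa)) ** 2) / (
        n * (1.0 - pe) ** 2
    )
    se = float(np.sqrt(max(var, 0.0)))
    return KappaResult(
        kappa=float(kappa), po=po, pe=pe, scheme=scheme, weights=w,
        se=se, ci_low=float(kappa - Z95 * se), ci_high=float(kappa + Z95 * se),
        band=interpret_kappa(float(kappa)), n=n, small_sample=n < 20,
    )


def cohen_kappa(table: CrossTable) -> KappaResult:
    """Ordinary (unweighted) Cohen's kappa: Po = trace/n, Pe = sum r_i c_i / n^2."""
    return _kappa(table, "none")


def weighted_kappa(table: CrossTable, scheme: WeightScheme = "linear") -> KappaResult:
    """Weighted Cohen's kappa; ``scheme`` is "linear" (default) or "quadratic"."""
    if scheme == "none":
        return cohen_kappa(table)
    return _kappa(table, scheme)


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean paired difference of codes with 95% limits of agreement.

    ``mean`` is (row rater - column rater), so positive values mean the
    row rater assigns higher severity. ``sd`` uses the n-1 denominator;
    limits are mean +/- 1.96 SD; ``ci_low``/``ci_high`` bound the mean
    itself (mean +/- 1.96 SD / sqrt(n)).
    """

    n: int
    mean: float
    sd: float
    loa_low: float
    loa_high: float
    ci_low: float
    ci_high: float
    max_abs_difference: int


def bland_altman(table: CrossTable, mask: CellMask | None = None) -> BlandAltmanResult:
    """Bland-Altman statistics of per-case rating-code differences.

    Differences are expanded from the cell counts (cell (i, j) contributes
    its count of differences i - j). Masked cells are removed first.
    """
    if mask is not None:
        table = apply_mask(table, mask)
    diffs = table.expand_differences()
    n = diffs.size
    if n == 0:
        raise AgreementError("no cases to analyse")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if n > 1 else 0.0
    half = Z95 * sd
    sem = sd / np.sqrt(n)
    return BlandAltmanResult(
        n=n, mean=mean, sd=sd,
        loa_low=mean - half, loa_high=mean + half,
        ci_low=float(mean - Z95 * sem), ci_high=float(mean + Z95 * sem),
        max_abs_difference=int(np.abs(diffs).max()),
    )


# ---------------------------------------------------------------------------
# proportions


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion x/n with its Wilson 95% score interval."""

    x: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float

    def as_percent(self) -> tuple[int, int, int]:
        """(estimate, low, high) rounded to integer percent, as reported."""
        return (
            int(round_half_up(100 * self.estimate)),
            int(round_half_up(100 * self.ci_low)),
            int(round_half_up(100 * self.ci_high)),
        )


def wilson_ci(x: int, n: int, z: float = Z95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    Unlike the Wald interval it never escapes [0, 1] and behaves sensibly
    at x = 0 or x = n (the lower bound is exactly 0 when x = 0).
    """
    if n < 1 or not 0 <= x <= n:
        raise AgreementError(f"invalid counts x={x}, n={n}")
    p = x / n
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = p + z2 / (2 * n)
    half = z * np.sqrt(p * (1 - p) / n + z2 / (4 * n * n))
    low = max((centre - half) / denom, 0.0)
    high = min((centre + half) / denom, 1.0)
    if x == 0:
        low = 0.0
    if x == n:
        high = 1.0
    return ProportionCI(x=int(x), n=int(n), estimate=p, ci_low=float(low), ci_high=float(high))


def concordance(table: CrossTable) -> ProportionCI:
    """Proportion of exact agreements (diagonal count / n) with Wilson CI."""
    return wilson_ci(table.diagonal, table.n)
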