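"""Bundled validation-study data and its full statistical re-analysis.

The decision model was validated on 200 clinically identified potential
drug-drug interactions, rated independently by (a) the decision model
itself, (b) a senior clinical pharmacologist and (c) the Micromedex
DrugDex database (MMX). Only the two aggregate 5x5 cross-tables (DM vs
pharmacologist, DM vs MMX) are available; the per-case drug identities
are not, so :func:`expand_fixture` synthesises per-case records consistent
with the cell counts when record-level input is needed.

Two kinds of cells are excluded in the second-stage analysis:

* *systematic differences* — the (D, C) cell of each table: the model
  escalates severity when complex monitoring is required or a safer
  alternative exists, a structural rule of the model rather than a rating
  error (30 cases vs the pharmacologist, 25 vs MMX);
* *no-rating cells* — cases where MMX returned no information (62 cases,
  column "unknown"); missing information is not evidence of safety, so
  these cannot be scored as disagreements with DM ratings B-E.

The pharmacologist-vs-MMX comparison is NOT re-analysed here: its joint
cross-table is not available and cannot be reconstructed from the two
bundled tables' marginals.

:func:`run_validation` recomputes every statistic of the study — kappas,
concordance with Wilson intervals, Bland-Altman limits before and after
exclusions, residual disagreement proportions — and checks them against
the study's reported values at their reported rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .agreement import (
    BlandAltmanResult,
    CellMask,
    CrossTable,
    KappaResult,
    ProportionCI,
    apply_mask,
    bland_altman,
    cohen_kappa,
    concordance,
    round_half_up,
    weighted_kappa,
    wilson_ci,
)
from .scales import DM_SCALE, MMX_SCALE, PHARMACOLOGIST_SCALE, RatingRecord

__all__ = [
    "StudyFixture",
    "ValidationReport",
    "load_fixture",
    "run_validation",
    "expand_fixture",
]

# DM (rows, A..E) x clinical pharmacologist (columns, aligned A..E), n = 200
_TABLE_DM_PHARM = np.array(
    [
        [18, 3, 0, 0, 0],
        [2, 10, 0, 0, 0],
        [0, 0, 49, 5, 0],
        [0, 1, 30, 60, 2],
        [0, 0, 0, 1, 19],
    ],
    dtype=np.int64,
)

# DM (rows, A..E) x MMX (columns, unknown..contraindicated), n = 200
_TABLE_DM_MMX = np.array(
    [
        [21, 0, 0, 0, 0],
        [8, 0, 4, 0, 0],
        [18, 4, 26, 6, 0],
        [32, 1, 25, 34, 1],
        [4, 0, 0, 3, 13],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class StudyFixture:
    """The study's two cross-tables plus the exclusion masks."""

    dm_vs_pharm: CrossTable
    dm_vs_mmx: CrossTable
    systematic_pharm: CellMask  # DM structurally more severe than expert
    systematic_mmx: CellMask    # DM structurally more severe than MMX
    no_rating_mmx: CellMask     # MMX returned no information

    def check(self) -> None:
        """Assert the fixture's documented marginals and mask totals."""
        t1, t2 = self.dm_vs_pharm, self.dm_vs_mmx
        expected = {
            "table 1 row totals": (t1.row_totals().tolist(), [21, 12, 54, 93, 20]),
            "table 1 column totals": (t1.col_totals().tolist(), [20, 14, 79, 66, 21]),
            "table 2 row totals": (t2.row_totals().tolist(), [21, 12, 54, 93, 20]),
            "table 2 column totals": (t2.col_totals().tolist(), [83, 5, 55, 43, 14]),
            "table totals": ([t1.n, t2.n], [200, 200]),
            "systematic cases vs pharmacologist": (
                [self.systematic_pharm.masked_count(t1)], [30]),
            "systematic cases vs MMX": ([self.systematic_mmx.masked_count(t2)], [25]),
            "MMX no-rating cases": ([self.no_rating_mmx.masked_count(t2)], [62]),
        }
        for what, (got, want) in expected.items():
            if got != want:
                raise ValueError(f"fixture invariant violated: {what}: {got} != {want}")


def load_fixture() -> StudyFixture:
    """The bundled validation data (checked against its invariants)."""
    fixture = StudyFixture(
        dm_vs_pharm=CrossTable(
            _TABLE_DM_PHARM, "DM", "pharmacologist",
            DM_SCALE.categories, PHARMACOLOGIST_SCALE.categories,
        ),
        dm_vs_mmx=CrossTable(
            _TABLE_DM_MMX, "DM", "MMX",
            DM_SCALE.categories, MMX_SCALE.categories,
        ),
        systematic_pharm=CellMask(
            [("D", "moderate")],
            reason="model escalates when monitoring is complex or an alternative exists",
        ),
        systematic_mmx=CellMask(
            [("D", "moderate")],
            reason="model escalates when monitoring is complex or an alternative exists",
        ),
        no_rating_mmx=CellMask(
            [("B", "unknown"), ("C", "unknown"), ("D", "unknown"), ("E", "unknown")],
            reason="MMX returned no information; not evidence of safety",
        ),
    )
    fixture.check()
    return fixture


@dataclass(frozen=True)
class Expectation:
    """A reported study value and the recomputed one, compared at the
    reported rounding."""

    name: str
    reported: object
    computed: object

    @property
    def ok(self) -> bool:
        return self.reported == self.computed


@dataclass(frozen=True)
class ComparisonResult:
    """All statistics for one rater pair, full sample and post-exclusion."""

    label: str
    table: CrossTable
    kappa: KappaResult
    kappa_weighted: KappaResult
    concordance: ProportionCI
    bland_altman: BlandAltmanResult
    excluded_n: int
    table_post: CrossTable
    kappa_post: KappaResult  # computed for completeness; no reported value
    bland_altman_post: BlandAltmanResult
    residual_disagreements: ProportionCI


@dataclass(frozen=True)
class ValidationReport:
    """Pure function of the fixture: every recomputable study statistic."""

    dm_vs_pharm: ComparisonResult
    dm_vs_mmx: ComparisonResult
    expectations: tuple[Expectation, ...]
    not_reproducible: tuple[str, ...]

    @property
    def all_ok(self) -> bool:
        return all(e.ok for e in self.expectations)


def _round2(x: float) -> float:
    return round_half_up(x, 2)


def _compare(label: str, table: CrossTable, masks: list[CellMask]) -> ComparisonResult:
    combined = CellMask(
        frozenset().union(*(m.cells for m in masks)), "combined exclusions"
    )
    table_post = apply_mask(table, combined)
    return ComparisonResult(
        label=label,
        table=table,
        kappa=cohen_kappa(table),
        kappa_weighted=weighted_kappa(table, "linear"),
        concordance=concordance(table),
        bland_altman=bland_altman(table),
        excluded_n=combined.masked_count(table),
        table_post=table_post,
        kappa_post=cohen_kappa(table_post),
        bland_altman_post=bland_altman(table_post),
        residual_disagreements=wilson_ci(
            table_post.n - table_post.diagonal, table.n
        ),
    )


def run_validation(fixture: StudyFixture | None = None) -> ValidationReport:
    """Recompute the whole validation analysis from the bundled tables.

    Residual (non-systematic) disagreement proportions use the full-study
    denominator of 200 cases, as in the original analysis ("14 of the 200
    ratings", "19 ... constitute 9.5%").
    """
    if fixture is None:
        fixture = load_fixture()
    fixture.check()

    pharm = _compare("DM vs pharmacologist", fixture.dm_vs_pharm, [fixture.systematic_pharm])
    mmx = _compare(
        "DM vs MMX", fixture.dm_vs_mmx, [fixture.no_rating_mmx, fixture.systematic_mmx]
    )

    expectations = (
        Expectation(
            "DM vs pharmacologist: kappa", 0.692, round_half_up(pharm.kappa.kappa, 3)
        ),
        Expectation(
            "DM vs pharmacologist: weighted kappa (linear)",
            0.805, round_half_up(pharm.kappa_weighted.kappa, 3),
        ),
        Expectation("DM vs pharmacologist: concordant cases", 156, pharm.concordance.x),
        Expectation(
            "DM vs pharmacologist: concordance % (Wilson 95% CI)",
            (78, 72, 83), pharm.concordance.as_percent(),
        ),
        Expectation(
            "DM vs pharmacologist: Bland-Altman mean difference",
            0.13, _round2(pharm.bland_altman.mean),
        ),
        Expectation(
            "DM vs pharmacologist: limits of agreement",
            (-0.8, 1.05), (_round2(pharm.bland_altman.loa_low), _round2(pharm.bland_altman.loa_high)),
        ),
        Expectation(
            "DM vs pharmacologist: residual disagreements",
            14, pharm.residual_disagreements.x,
        ),
        Expectation(
            "DM vs pharmacologist: residual disagreement % (Wilson 95% CI)",
            (7, 4, 11), pharm.residual_disagreements.as_percent(),
        ),
        Expectation("DM vs MMX: kappa", 0.315, round_half_up(mmx.kappa.kappa, 3)),
        Expectation(
            "DM vs MMX: weighted kappa (linear)",
            0.363, round_half_up(mmx.kappa_weighted.kappa, 3),
        ),
        Expectation("DM vs MMX: concordant cases", 94, mmx.concordance.x),
        Expectation(
            "DM vs MMX: concordance % (Wilson 95% CI)",
            (47, 40, 54), mmx.concordance.as_percent(),
        ),
        Expectation(
            "DM vs MMX: Bland-Altman mean difference",
            0.9, round_half_up(mmx.bland_altman.mean, 1),
        ),
        Expectation(
            "DM vs MMX: limits of agreement",
            (-1.6, 3.4),
            (
                round_half_up(mmx.bland_altman.loa_low, 1),
                round_half_up(mmx.bland_altman.loa_high, 1),
            ),
        ),
        Expectation("DM vs MMX: cases excluded", 62 + 25, mmx.excluded_n),
        Expectation("DM vs MMX: post-exclusion n", 113, mmx.bland_altman_post.n),
        Expectation(
            "DM vs MMX: post-exclusion mean difference",
            -0.02, _round2(mmx.bland_altman_post.mean),
        ),
        Expectation(
            "DM vs MMX: post-exclusion limits of agreement",
            (-0.89, 0.85),
            (_round2(mmx.bland_altman_post.loa_low), _round2(mmx.bland_altman_post.loa_high)),
        ),
        Expectation(
            "DM vs MMX: residual disagreements", 19, mmx.residual_disagreements.x
        ),
        Expectation(
            "DM vs MMX: residual disagreement % (Wilson 95% CI, of 200; estimate 9.5%)",
            (10, 6, 14), mmx.residual_disagreements.as_percent(),
        ),
    )

    not_reproducible = (
        "pharmacologist vs MMX comparison (89 agreements, 45% [38, 51]; "
        "Bland-Altman 0.8, limits [-1.5, 3.1]): joint cross-table not "
        "published, cannot be reconstructed from marginals",
        "kappa confidence intervals as originally reported: interval method "
        "unstated (the asymptotic intervals computed here are informational)",
    )
    return ValidationReport(
        dm_vs_pharm=pharm,
        dm_vs_mmx=mmx,
        expectations=expectations,
        not_reproducible=not_reproducible,
    )


def expand_fixture(
    fixture: StudyFixture | None = None, seed: int = 0
) -> dict[str, list[RatingRecord]]:
    """Synthesise per-case rating records consistent with the cell counts.

    The real drug identities are unavailable, so cases get synthetic ids
    ``case_0001``... and placeholder drug labels; the case-to-cell
    assignment order is shuffled with ``seed`` to avoid accidental
    structure. Cross-tabulating the output reproduces the fixture tables
    exactly.
    """
    if fixture is None:
        fixture = load_fixture()
    rng = np.random.default_rng(seed)
    out: dict[str, list[RatingRecord]] = {"DM": [], "pharmacologist": [], "MMX": []}

    t1, t2 = fixture.dm_vs_pharm, fixture.dm_vs_mmx
    # Per-case DM codes are shared by both tables; independently pair the
    # DM ratings with pharmacologist and MMX ratings row by row (the joint
    # three-way distribution is unknown and not needed for pairwise tables).
    case = 0
    for i, label_dm in enumerate(t1.row_labels):
        pharm_codes = np.repeat(np.arange(t1.k), t1.counts[i])
        mmx_codes = np.repeat(np.arange(t2.k), t2.counts[i])
        assert pharm_codes.size == mmx_codes.size  # equal row totals
        rng.shuffle(pharm_codes)
        rng.shuffle(mmx_codes)
        for jp, jm in zip(pharm_codes, mmx_codes):
            case += 1
            cid = f"case_{case:04d}"
            drug_a, drug_b = f"drug_{case:04d}a", f"drug_{case:04d}b"
            out["DM"].append(RatingRecord(cid, drug_a, drug_b, "DM", label_dm))
            out["pharmacologist"].append(
                RatingRecord(cid, drug_a, drug_b, "pharmacologist", t1.col_labels[jp])
            )
            out["MMX"].append(
                RatingRecord(cid, drug_a, drug_b, "MMX", t2.col_labels[jm])
            )
    return out
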