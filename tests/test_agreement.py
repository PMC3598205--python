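"""Agreement statistics against independent oracles.

Cell-count implementations of kappa and Bland-Altman are checked against
per-case computations on the expanded rating lists (sklearn's
cohen_kappa_score and plain numpy); the Wilson interval is checked against
statsmodels. Structural identities (kappa = 1 on diagonal tables, 0 on
independence tables, identity weights = unweighted) are asserted exactly.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

from conftest import random_table
from ddirate.agreement import (
    AgreementError,
    CellMask,
    CrossTable,
    apply_mask,
    bland_altman,
    build_cross_table,
    cohen_kappa,
    concordance,
    interpret_kappa,
    round_half_up,
    weight_matrix,
    weighted_kappa,
    wilson_ci,
)
from ddirate.scales import DM_SCALE, RatingRecord

LABELS = DM_SCALE.categories


def table_from(counts):
    counts = np.asarray(counts)
    k = counts.shape[0]
    return CrossTable(counts, "A", "B", LABELS[:k], LABELS[:k])


def expand(table):
    """Per-case (row code, col code) lists implied by the cell counts."""
    rows, cols = [], []
    for i in range(table.k):
        for j in range(table.k):
            rows += [i + 1] * table.counts[i, j]
            cols += [j + 1] * table.counts[i, j]
    return np.array(rows), np.array(cols)


class TestCrossTable:
    def test_build_from_records_roundtrip(self, rng):
        counts = random_table(rng)
        rows, cols = expand(table_from(counts))
        recs_a = [
            RatingRecord(f"c{i}", "x", "y", "A", LABELS[r - 1])
            for i, r in enumerate(rows)
        ]
        recs_b = [
            RatingRecord(f"c{i}", "x", "y", "B", LABELS[c - 1])
            for i, c in enumerate(cols)
        ]
        table = build_cross_table(recs_a, recs_b, DM_SCALE, DM_SCALE)
        assert np.array_equal(table.counts, counts)

    def test_disjoint_case_ids_rejected(self):
        a = [RatingRecord("c1", "x", "y", "A", "A")]
        b = [RatingRecord("c2", "x", "y", "B", "A")]
        with pytest.raises(AgreementError, match="case ids differ"):
            build_cross_table(a, b, DM_SCALE, DM_SCALE)

    def test_duplicate_rating_rejected(self):
        a = [RatingRecord("c1", "x", "y", "A", "A"),
             RatingRecord("c1", "x", "y", "A", "B")]
        with pytest.raises(AgreementError, match="more than once"):
            build_cross_table(a, a[:1], DM_SCALE, DM_SCALE)

    def test_negative_counts_rejected(self):
        with pytest.raises(AgreementError, match="non-negative"):
            table_from([[1, -1], [0, 1]])


class TestKappa:
    def test_diagonal_table_perfect_agreement(self):
        table = table_from(np.diag([3, 1, 4, 1, 5]))
        for result in (cohen_kappa(table), weighted_kappa(table, "linear"),
                       weighted_kappa(table, "quadratic")):
            assert result.kappa == pytest.approx(1.0)
        assert cohen_kappa(table).se == pytest.approx(0.0)

    def test_marginal_product_table_chance_agreement(self):
        # joint counts equal to the outer product of the marginals
        table = table_from(np.outer([1, 2, 3, 4, 10], [5, 15, 10, 5, 5]))
        assert cohen_kappa(table).kappa == pytest.approx(0.0, abs=1e-12)
        assert weighted_kappa(table, "linear").kappa == pytest.approx(0.0, abs=1e-12)

    def test_identity_weights_equal_unweighted(self, rng):
        for _ in range(25):
            table = table_from(random_table(rng))
            plain = cohen_kappa(table)
            via_weights = weighted_kappa(table, "none")
            assert via_weights.kappa == plain.kappa
            assert np.array_equal(plain.weights, np.eye(5))

    def test_brute_force_oracle_random_tables(self, rng):
        # cell-count formulas vs per-case computation (sklearn) to 1e-12
        checked = 0
        for _ in range(40):
            table = table_from(random_table(rng, n_max=50))
            rows, cols = expand(table)
            if len(set(rows) | set(cols)) < 2:
                continue
            ours = cohen_kappa(table)
            if ours.degenerate:
                continue
            ref = cohen_kappa_score(rows, cols, labels=list(range(1, 6)))
            assert ours.kappa == pytest.approx(ref, abs=1e-12)
            ref_lin = cohen_kappa_score(
                rows, cols, labels=list(range(1, 6)), weights="linear"
            )
            assert weighted_kappa(table, "linear").kappa == pytest.approx(
                ref_lin, abs=1e-12
            )
            checked += 1
        assert checked >= 20

    def test_degenerate_single_category_flagged(self):
        table = table_from(np.diag([7, 0, 0, 0, 0]))
        result = cohen_kappa(table)
        assert result.degenerate and np.isnan(result.kappa)

    def test_negative_kappa_reported_as_less_than_chance(self):
        table = table_from(np.fliplr(np.diag([4, 4, 4, 4, 4])))
        result = cohen_kappa(table)
        assert result.kappa < 0
        assert result.band == "less than chance"

    def test_interpretation_bands(self):
        assert interpret_kappa(0.1) == "slight agreement"
        assert interpret_kappa(0.315) == "fair agreement"
        assert interpret_kappa(0.5) == "moderate agreement"
        assert interpret_kappa(0.692) == "substantial agreement"
        assert interpret_kappa(0.95) == "perfect agreement"

    def test_linear_weighted_intermediates_on_expert_table(self, fixture):
        # hand-computed from the cell counts: Po_w = 188.75/200,
        # Pe_w = 28446.5/40000, kappa_w = 0.8053
        result = weighted_kappa(fixture.dm_vs_pharm, "linear")
        assert result.po * 200 == pytest.approx(188.75)
        assert result.pe * 40000 == pytest.approx(28446.5)
        assert result.kappa == pytest.approx(0.8053, abs=5e-5)

    def test_weight_matrix_shapes(self):
        linear = weight_matrix(5, "linear")
        assert linear[0, 0] == 1.0
        assert linear[0, 4] == 0.0
        assert linear[0, 1] == pytest.approx(0.75)
        quad = weight_matrix(5, "quadratic")
        assert quad[0, 1] == pytest.approx(1 - 1 / 16)


class TestBlandAltman:
    def test_brute_force_oracle_random_tables(self, rng):
        for _ in range(25):
            table = table_from(random_table(rng, n_max=50))
            rows, cols = expand(table)
            diffs = rows - cols
            result = bland_altman(table)
            assert result.mean == pytest.approx(diffs.mean(), abs=1e-12)
            sd = diffs.std(ddof=1) if len(diffs) > 1 else 0.0
            assert result.sd == pytest.approx(sd, abs=1e-12)
            assert result.loa_low == pytest.approx(result.mean - 1.96 * sd, abs=1e-12)

    def test_diagonal_table_zero_differences(self):
        result = bland_altman(table_from(np.diag([2, 2, 2, 2, 2])))
        assert (result.mean, result.sd) == (0.0, 0.0)
        assert (result.loa_low, result.loa_high) == (0.0, 0.0)

    def test_mask_removes_cases_before_computing(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[3, 2] = 10  # D vs C: +1 differences
        counts[0, 0] = 10
        full = bland_altman(table_from(counts))
        masked = bland_altman(table_from(counts), CellMask([("D", "C")]))
        assert full.mean == pytest.approx(0.5)
        assert masked.mean == 0.0 and masked.n == 10

    def test_empty_after_masking_rejected(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 1] = 3
        with pytest.raises(AgreementError, match="empty"):
            bland_altman(table_from(counts), CellMask([("A", "B")]))


class TestMask:
    def test_mask_conserves_counts(self, rng):
        for _ in range(10):
            table = table_from(random_table(rng))
            mask = CellMask([("D", "C"), ("B", "A"), ("E", "E")])
            if mask.masked_count(table) == table.n:
                continue
            masked = apply_mask(table, mask)
            assert table.n == masked.n + mask.masked_count(table)
            # original untouched
            assert table.counts[3, 2] == table.to_frame().loc["D", "C"]

    def test_empty_mask_is_identity(self, fixture):
        table = fixture.dm_vs_pharm
        assert np.array_equal(
            apply_mask(table, CellMask([])).counts, table.counts
        )

    def test_out_of_bounds_mask_rejected(self, fixture):
        with pytest.raises(AgreementError, match="outside table bounds"):
            apply_mask(fixture.dm_vs_pharm, CellMask([("D", "Z")]))


class TestWilson:
    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (14, 200, (7, 4, 11)),    # residual DM/pharmacologist disagreements
            (19, 200, (10, 6, 14)),   # residual DM/MMX disagreements (9.5%)
            (156, 200, (78, 72, 83)),
            (94, 200, (47, 40, 54)),
        ],
    )
    def test_reported_intervals_at_integer_percent(self, x, n, expected):
        assert wilson_ci(x, n).as_percent() == expected

    def test_zero_count_lower_bound_is_zero(self):
        ci = wilson_ci(0, 10)
        assert ci.ci_low == 0.0 and ci.estimate == 0.0 and ci.ci_high > 0

    @given(x=st.integers(0, 500), n=st.integers(1, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_statsmodels_and_contains_estimate(self, x, n):
        x = min(x, n)
        ci = wilson_ci(x, n)
        low, high = proportion_confint(x, n, alpha=0.05, method="wilson")
        # statsmodels uses z = 1.95996...; we use the conventional 1.96
        assert ci.ci_low == pytest.approx(low, abs=1e-4)
        assert ci.ci_high == pytest.approx(high, abs=1e-4)
        assert 0.0 <= ci.ci_low <= ci.estimate <= ci.ci_high <= 1.0

    def test_interval_shrinks_with_n_at_fixed_proportion(self):
        widths = [
            wilson_ci(7 * m, 100 * m).ci_high - wilson_ci(7 * m, 100 * m).ci_low
            for m in (1, 4, 16, 64)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_invalid_counts_rejected(self):
        with pytest.raises(AgreementError):
            wilson_ci(5, 0)
        with pytest.raises(AgreementError):
            wilson_ci(-1, 10)


def test_concordance_is_diagonal_proportion(fixture):
    ci = concordance(fixture.dm_vs_pharm)
    assert (ci.x, ci.n) == (156, 200)


def test_round_half_up_convention():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(9.5) == 10.0
    assert round_half_up(-0.885, 2) == -0.89
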