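"""Discordance labeling, error tabulation and the chi-square test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from hscr_dss import (
    Cause,
    ContingencyTable,
    DegenerateTableError,
    DiscordanceLabel,
    ImageSetRecord,
    ValidationError,
    bonferroni,
    chi_square_independence,
    error_contingency,
    label_discordance,
    tabulate_discordance,
)


def iset(pathologist, dsa, causes=(), idx=1, case_id="c"):
    return ImageSetRecord(
        case_id=case_id, set_index=idx, dsa_score=dsa,
        pathologist_score=pathologist, cause_annotations=frozenset(causes),
    )


class TestLabelDiscordance:
    @pytest.mark.parametrize(
        "pathologist,dsa,expected",
        [
            (5, 0.29, DiscordanceLabel.FALSE_NEGATIVE),
            (1, 0.71, DiscordanceLabel.FALSE_POSITIVE),
            (5, 0.30, DiscordanceLabel.CONCORDANT),  # strict boundary
            (1, 0.70, DiscordanceLabel.CONCORDANT),  # strict boundary
            (5, 0.95, DiscordanceLabel.CONCORDANT),
            (1, 0.05, DiscordanceLabel.CONCORDANT),
            (4, 0.0, DiscordanceLabel.CONCORDANT),  # only certain scores qualify
            (2, 1.0, DiscordanceLabel.CONCORDANT),
        ],
    )
    def test_cutoff_rule(self, pathologist, dsa, expected):
        assert label_discordance(iset(pathologist, dsa)) is expected

    @given(st.integers(1, 5), st.floats(0, 1))
    def test_fp_and_fn_mutually_exclusive(self, pathologist, dsa):
        # the two conditions require different pathologist scores, so no
        # set can satisfy both
        label = label_discordance(iset(pathologist, dsa))
        if label is DiscordanceLabel.FALSE_NEGATIVE:
            assert pathologist == 5
        if label is DiscordanceLabel.FALSE_POSITIVE:
            assert pathologist == 1


def build_stratum(n_sets, n_fn=0, n_fp=0, fn_causes=(), fp_causes=(), case_id="c"):
    """Construct a stratum with exact FN/FP counts; fillers are concordant."""
    sets = []
    for i in range(n_fn):
        sets.append(iset(5, 0.1, causes=fn_causes, idx=i + 1, case_id=case_id))
    for i in range(n_fp):
        sets.append(iset(1, 0.9, causes=fp_causes, idx=n_fn + i + 1, case_id=case_id))
    for i in range(n_sets - n_fn - n_fp):
        sets.append(iset(3, 0.5, idx=n_fn + n_fp + i + 1, case_id=case_id))
    return sets


class TestTabulateDiscordance:
    def test_center_a_shaped_rates(self):
        """675 sets with 46 false negatives gives a 6.81% FN rate."""
        [t] = tabulate_discordance({"center_a": build_stratum(675, n_fn=46, n_fp=2)})
        assert t.fn_rate == pytest.approx(100 * 46 / 675)
        assert round(t.fn_rate, 2) == 6.81
        assert t.total_error_rate == pytest.approx(t.fp_rate + t.fn_rate)

    def test_scanner_shaped_total_error(self):
        """447 sets with 40 FP + 4 FN gives a 9.8% total error rate."""
        [t] = tabulate_discordance({"histech3d": build_stratum(447, n_fn=4, n_fp=40)})
        assert round(t.total_error_rate, 1) == 9.8
        assert (t.n_fp, t.n_fn) == (40, 4)

    def test_clean_stratum_has_zero_rates(self):
        [t] = tabulate_discordance({"s": build_stratum(100)})
        assert t.fp_rate == t.fn_rate == t.total_error_rate == 0.0

    def test_empty_stratum_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            tables = tabulate_discordance({"empty": [], "ok": build_stratum(10)})
        assert [t.stratum for t in tables] == ["ok"]
        assert "empty" in caplog.text

    def test_cause_tallies(self):
        # a set may carry several causes; unannotated errors count as unknown
        sets = build_stratum(
            10, n_fn=2, n_fp=1,
            fn_causes=(Cause.TECHNICAL, Cause.MISSING_SENS_SPEC),
        )
        [t] = tabulate_discordance({"s": sets})
        assert t.fn_causes[Cause.TECHNICAL] == 2
        assert t.fn_causes[Cause.MISSING_SENS_SPEC] == 2
        assert t.fp_causes[Cause.UNKNOWN] == 1
        # concordant sets contribute nothing
        assert sum(t.fp_causes.values()) == 1

    @given(st.lists(st.tuples(st.integers(1, 5), st.floats(0, 1)), min_size=1, max_size=50))
    def test_rate_additivity_and_bounds(self, pairs):
        sets = [iset(p, d, idx=i + 1) for i, (p, d) in enumerate(pairs)]
        [t] = tabulate_discordance({"s": sets})
        assert t.total_error_rate == pytest.approx(t.fp_rate + t.fn_rate)
        assert t.n_fn <= sum(p == 5 for p, _ in pairs)
        assert t.n_fp <= sum(p == 1 for p, _ in pairs)
        assert t.n_fp + t.n_fn <= t.n_sets


def ctable(rows, row_labels=None, col_labels=None):
    rows = np.asarray(rows)
    return ContingencyTable(
        counts=rows,
        row_labels=row_labels or tuple(f"r{i}" for i in range(rows.shape[0])),
        col_labels=col_labels or tuple(f"c{i}" for i in range(rows.shape[1])),
    )


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        stat, df, p = chi_square_independence(ctable([[10, 10], [10, 10]]))
        assert stat == 0.0
        assert (df, p) == (1, 1.0)

    def test_hand_computed_2x2(self):
        # expected counts [[30, 70], [30, 70]]; sum (O-E)^2/E = 200/21
        stat, df, _ = chi_square_independence(ctable([[20, 80], [40, 60]]))
        assert stat == pytest.approx(200 / 21)
        assert stat == pytest.approx(9.5238, abs=1e-4)
        assert df == 1

    def test_df_formula(self):
        _, df, _ = chi_square_independence(ctable([[5, 3, 2], [1, 7, 4]]))
        assert df == 2

    @pytest.mark.parametrize(
        "rows",
        [[[20, 80], [40, 60]], [[5, 3, 2], [1, 7, 4]], [[46, 2], [41, 5], [25, 3], [3, 23]]],
    )
    def test_matches_scipy_contingency(self, rows):
        """Independent cross-check against scipy's full contingency routine."""
        stat, df, p = chi_square_independence(ctable(rows))
        ref = chi2_contingency(np.asarray(rows), correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_yates_matches_scipy_correction(self):
        stat, _, p = chi_square_independence(ctable([[20, 80], [40, 60]]), yates=True)
        ref = chi2_contingency(np.array([[20, 80], [40, 60]]), correction=True)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_permutation_invariance_and_scaling(self):
        base = [[12, 30, 7], [25, 4, 18]]
        stat, _, _ = chi_square_independence(ctable(base))
        perm = [[7, 12, 30], [18, 25, 4]]  # column permutation
        stat_p, _, _ = chi_square_independence(ctable(perm))
        assert stat_p == pytest.approx(stat)
        scaled = [[3 * x for x in row] for row in base]
        stat_s, _, _ = chi_square_independence(ctable(scaled))
        assert stat_s == pytest.approx(3 * stat)

    def test_p_monotone_in_statistic(self):
        # stronger association at the same margins -> smaller p
        _, _, p_weak = chi_square_independence(ctable([[45, 55], [55, 45]]))
        _, _, p_strong = chi_square_independence(ctable([[20, 80], [80, 20]]))
        assert p_strong < p_weak

    def test_degenerate_and_invalid_tables(self):
        with pytest.raises(DegenerateTableError):
            chi_square_independence(ctable([[0, 0], [5, 5]]))
        with pytest.raises(ValidationError):
            ctable([[1, -2], [3, 4]])
        with pytest.raises(ValidationError):
            ctable([[1.5, 2.2], [3.3, 4.4]])
        with pytest.raises(ValidationError):
            ctable([[1, 2]])  # fewer than 2 rows


def test_error_contingency_shape():
    tables = tabulate_discordance(
        {
            "a": build_stratum(100, n_fn=10, n_fp=2),
            "b": build_stratum(100, n_fn=1, n_fp=9),
        }
    )
    ct = error_contingency(tables)
    assert ct.counts.tolist() == [[10, 2], [1, 9]]
    assert ct.col_labels == ("false_negative", "false_positive")


def test_bonferroni_clips_at_one():
    assert bonferroni([0.01, 0.4, 0.9]) == [0.03, 1.0, 1.0]
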