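"""Cohort table parsing and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from imlen.cohort_stats import (
    CohortTable,
    EXPECTED_COUNTS,
    _exact_signrank_cdf,
    cohort_report,
    error_summary,
    load_cohort,
    parse_iml,
    report_text,
    rmse,
    wilcoxon_signed_rank,
)
from imlen.errors import CohortIntegrityWarning, CohortParseError


@pytest.fixture(scope="module")
def cohort():
    return load_cohort()


class TestParseIml:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("3–4", 3.5),
            ("8.8–10.8", 9.8),
            ("4.8-5", 4.9),           # ASCII hyphen accepted
            ("0 (or “Short”)", 0.0),
            ("Short", 0.0),
            ("7", 7.0),
            (7.0, 7.0),
        ],
    )
    def test_conventions(self, raw, expected):
        assert parse_iml(raw) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(0, 50, allow_nan=False))
    def test_idempotent_on_numeric(self, value):
        assert parse_iml(parse_iml(value)) == parse_iml(value)

    @pytest.mark.parametrize("raw", ["", "n/a", "three", "-5"])
    def test_unparseable(self, raw):
        with pytest.raises(CohortParseError):
            parse_iml(raw)


class TestFixture:
    def test_counts(self, cohort):
        assert cohort.counts["total"] == EXPECTED_COUNTS["total"]
        assert cohort.counts["R-AAOCA"] == EXPECTED_COUNTS["R-AAOCA"]
        assert cohort.counts["L-AAOCA"] == EXPECTED_COUNTS["L-AAOCA"]

    def test_mixed_anomaly_string_maps_to_right(self, cohort):
        row = cohort.records[cohort.records["anomaly"].str.contains("MB")]
        assert (row["anomaly_class"] == "R-AAOCA").all()

    def test_raw_strings_retained(self, cohort):
        assert "3–4" in set(cohort.records["radiologic"])

    def test_truncated_table_warns_but_computes(self, cohort, tmp_path):
        path = tmp_path / "short.csv"
        cohort.records.iloc[:57][
            ["patient", "anomaly", "radiologic", "computational", "surgical"]
        ].to_csv(path, index=False)
        with pytest.warns(CohortIntegrityWarning):
            table = CohortTable.from_csv(path)
        report = cohort_report(table)
        assert report["counts"]["total"] == 57

    def test_missing_column_is_an_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient,anomaly\n1,L-AAOCA\n")
        with pytest.raises(CohortParseError):
            CohortTable.from_csv(path)


class TestRmseAndErrors:
    def test_identical_inputs(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert error_summary([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_single_pair(self):
        assert rmse([3.0], [0.0]) == 3.0

    def test_left_cohort_rmse(self, cohort):
        sub = cohort.subset("L-AAOCA")
        assert rmse(sub["computational_mm"], sub["surgical_mm"]) == pytest.approx(
            3.6, abs=0.05
        )

    def test_left_cohort_error_summary(self, cohort):
        sub = cohort.subset("L-AAOCA")
        mean_c, sd_c = error_summary(sub["computational_mm"], sub["surgical_mm"])
        mean_r, sd_r = error_summary(sub["radiologic_mm"], sub["surgical_mm"])
        assert mean_c == pytest.approx(0.7, abs=0.05)
        assert sd_c == pytest.approx(3.75, abs=0.05)
        assert mean_r == pytest.approx(-2.0, abs=0.05)
        assert sd_r == pytest.approx(4.5, abs=0.05)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rmse_dominates_mean_error(self, seed):
        rng = np.random.default_rng(seed)
        est = rng.normal(5, 3, size=12)
        ref = rng.normal(5, 3, size=12)
        mean, _ = error_summary(est, ref)
        assert rmse(est, ref) ** 2 >= mean**2 - 1e-12


class TestWilcoxon:
    def test_tiny_enumeration(self):
        # all three differences positive: two-sided p = 2/2^3
        stat, p = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0], mode="exact")
        assert stat == 0.0
        assert p == pytest.approx(0.25)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            x = rng.normal(0, 1, size=12)
            y = rng.normal(0.3, 1, size=12)
            stat, p = wilcoxon_signed_rank(x, y, mode="exact")
            ref = sps.wilcoxon(x, y, method="exact")
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approx_matches_scipy(self):
        rng = np.random.default_rng(29)
        x = rng.normal(0, 1, size=49)
        y = rng.normal(0.2, 1, size=49)
        _, p = wilcoxon_signed_rank(x, y, mode="approx")
        ref = sps.wilcoxon(x, y, method="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_and_approx_agree_at_n49(self):
        # sanity bound at fixed seeds: exact distribution (internal DP, no
        # size cap) vs normal approximation within 0.02 without heavy ties
        rng = np.random.default_rng(31)
        for _ in range(3):
            x = rng.normal(0, 1, size=49)
            y = rng.normal(0.25, 1, size=49)
            d = x - y
            ranks = sps.rankdata(np.abs(d))
            w_plus = 2 * int(round(ranks[d > 0].sum()))
            counts = _exact_signrank_cdf(np.rint(2 * ranks).astype(int))
            total = counts.sum()
            p_exact = min(
                1.0,
                2 * min(counts[: w_plus + 1].sum(), counts[w_plus:].sum()) / total,
            )
            _, p_approx = wilcoxon_signed_rank(x, y, mode="approx")
            assert abs(p_exact - p_approx) < 0.02

    def test_exact_mode_size_cap(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, x + 1, mode="exact")


class TestReport:
    def test_report_structure_and_text(self, cohort):
        report = cohort_report(cohort)
        assert set(report["groups"]) == {"overall", "L-AAOCA", "R-AAOCA"}
        text = report_text(report)
        assert "58 patients" in text
        assert "3.4" in text  # overall computational RMSE
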