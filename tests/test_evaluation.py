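"""Evaluation layer: Wilson intervals, thresholds, combinations, subgroups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragsignal import evaluation, io
from fragsignal.evaluation import (
    EvalConfig,
    calibrate_threshold,
    classify,
    combine,
    literature_comparator,
    reproducibility,
    round_half_away,
    subgroup_partition,
    subgroup_report,
    wilson_ci,
)


def wilson_oracle(k, n, z=None):
    """Wilson bounds as roots of the score-test quadratic (independent
    route: solve (1 + z^2/n) q^2 - (2p + z^2/n) q + p^2 = 0 with the
    numerically stable quadratic formula)."""
    import math

    from scipy.stats import norm

    if z is None:
        z = norm.ppf(0.975)  # 1.959964 at printed precision
    p = k / n
    a = 1 + z * z / n
    b = -(2 * p + z * z / n)
    c = p * p
    disc = math.sqrt(max(b * b - 4 * a * c, 0.0))
    q = -(b - disc) / 2  # b <= 0 here
    hi = q / a
    lo = c / q if q else 0.0
    return 100 * lo, 100 * hi


class TestWilson:
    def test_matches_quadratic_oracle_for_all_small_tables(self):
        for n in range(1, 201):
            for k in (0, 1, n // 2, n - 1, n):
                lo, hi = wilson_ci(k, n)
                olo, ohi = wilson_oracle(k, n)
                assert lo == pytest.approx(olo, abs=1e-10)
                assert hi == pytest.approx(ohi, abs=1e-10)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(9, 40), (32, 32), (30, 32), (0, 10), (3, 7)]:
            lo, hi = wilson_ci(k, n)
            slo, shi = proportion_confint(k, n, method="wilson")
            assert lo == pytest.approx(100 * slo, abs=1e-8)
            assert hi == pytest.approx(100 * shi, abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 3)


class TestCalibrateThreshold:
    def test_one_exceedance_allowed_at_90_percent(self):
        controls = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        assert calibrate_threshold(controls, 0.9) == pytest.approx(0.8)

    def test_perfect_specificity_returns_max(self):
        assert calibrate_threshold([0.2, 0.5, 0.4], 1.0) == pytest.approx(0.5)

    def test_all_equal_controls(self):
        assert calibrate_threshold([0.3] * 10, 0.9) == pytest.approx(0.3)

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([], 0.99)

    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=60),
        spec=st.floats(0.5, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_over_candidates(self, scores, spec):
        """The returned threshold is the smallest control score whose
        strict-exceedance count stays within the allowed budget."""
        import math

        t = calibrate_threshold(scores, spec)
        arr = np.asarray(scores)
        n = len(arr)
        m = min(int(math.ceil(n * (1 - spec) - 1e-12)), n - 1)
        candidates = [s for s in np.sort(arr) if (arr > s).sum() <= m]
        assert t == pytest.approx(min(candidates))


@pytest.fixture(scope="module")
def study():
    scores = io.load_study_scores()
    cohort = io.CohortTable(
        scores.drop(columns=["signal_score", "gas_score", "protein17_score"])
    )
    return scores, cohort


class TestClassifyCombine:
    def test_published_per_assay_case_positives(self, study):
        scores, _ = study
        calls = classify(scores)
        is_case = scores.set_index("sample_id")["group"] == "case"
        assert int(calls.loc[is_case, "signal"].sum()) == 9
        assert int(calls.loc[is_case, "gas"].sum()) == 11
        assert int(calls.loc[is_case, "protein17"].sum()) == 5

    def test_strict_mode_excludes_rounded_tie(self, study):
        scores, _ = study
        calls = classify(scores, EvalConfig(mode="raw_strict"))
        is_case = scores.set_index("sample_id")["group"] == "case"
        # the case with a printed protein score exactly at the 0.96
        # threshold counts only under the printed-rounded convention
        assert int(calls.loc[is_case, "protein17"].sum()) == 4

    def test_published_combination_counts(self, study):
        scores, _ = study
        calls = classify(scores)
        is_case = (scores.set_index("sample_id")["group"] == "case").to_numpy()
        expected = {
            ("signal", "protein17"): 12,
            ("signal", "gas"): 13,
            ("protein17", "gas"): 14,
            ("signal", "protein17", "gas"): 16,
        }
        for combo, count in expected.items():
            assert int(combine(calls, list(combo))[is_case].sum()) == count

    def test_all_negative_combination(self):
        calls = pd.DataFrame({"signal": [False], "gas": [False], "protein17": [np.nan]})
        assert not combine(calls, ["signal", "gas", "protein17"]).iloc[0]

    def test_empty_assay_set_rejected(self, study):
        calls = classify(study[0])
        with pytest.raises(ValueError):
            combine(calls, [])

    def test_or_rule_monotonicity(self, study):
        """Adding an assay can only raise sensitivity and lower specificity."""
        scores, _ = study
        calls = classify(scores)
        is_case = scores.set_index("sample_id")["group"] == "case"
        sets = [("signal",), ("signal", "gas"), ("signal", "gas", "protein17")]
        prev_sens, prev_spec = -1.0, 101.0
        for combo in sets:
            call = combine(calls, list(combo))
            sens = call[is_case].mean() * 100
            spec = 100 - call[~is_case].mean() * 100
            assert sens >= prev_sens
            assert spec <= prev_spec
            prev_sens, prev_spec = sens, spec


class TestSubgroups:
    def test_partition_sizes_match_study(self, study):
        _, cohort = study
        part = subgroup_partition(cohort)
        counts = part.value_counts()
        assert counts["hgd"] == 8
        assert counts["ge2cm"] == 19
        assert counts["ge1lt2cm"] == 13

    def test_hgd_has_priority_over_size(self, study):
        _, cohort = study
        part = subgroup_partition(cohort)
        # a 6 cm adenoma with high-grade dysplasia belongs to HGD only
        assert part["AA12"] == "hgd"
        # low dysplasia at 1.6 cm falls in the 1-2 cm band
        assert part["AA04"] == "ge1lt2cm"

    def test_unassignable_case_rejected(self):
        t = pd.DataFrame(
            {
                "sample_id": ["x"],
                "group": ["case"],
                "size_cm": [0.5],
                "histology": ["tubular"],
                "dysplasia": ["low"],
            }
        )
        with pytest.raises(ValueError, match="not assignable"):
            subgroup_partition(io.CohortTable(t))


class TestComparators:
    def test_fit_and_stool_dna_expected_detections(self):
        sizes = (8, 19, 13)
        counts, overall = literature_comparator(sizes, (46.0, 42.0, 21.0))
        assert counts == [4, 8, 3]
        assert overall == pytest.approx(37.5)
        counts, overall = literature_comparator(sizes, (69.0, 68.0, 38.0))
        assert counts == [6, 13, 5]
        assert overall == pytest.approx(60.0)

    def test_zero_sensitivities(self):
        counts, overall = literature_comparator((8, 19, 13), (0, 0, 0))
        assert sum(counts) == 0 and overall == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            literature_comparator((8, 19), (50, 42, 23))


class TestReproducibility:
    def test_identical_pairs_give_r_of_one(self):
        s = np.linspace(0.02, 0.9, 20)
        assert reproducibility(s, s)["r"] == pytest.approx(1.0)

    def test_independent_pairs_give_near_zero_r(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0.02, 1, 1000), rng.uniform(0.02, 1, 1000)
        assert abs(reproducibility(a, b)["r"]) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            reproducibility([0.5] * 5, [0.2, 0.3, 0.4, 0.5, 0.6])

    def test_concordance_counts(self):
        a = [0.9, 0.9, 0.1, 0.1]
        b = [0.95, 0.2, 0.05, 0.15]
        out = reproducibility(a, b, threshold=0.5)
        assert out["concordant_positive"] == 1
        assert out["concordant_negative"] == 2
        assert out["discordant"] == 1


def test_round_half_away():
    assert round_half_away(23.05, 1) == pytest.approx(23.1)
    assert round_half_away(7.65, 1) == pytest.approx(7.7)
    assert round_half_away(-2.45, 1) == pytest.approx(-2.5)


def test_subgroup_report_specificity_columns(study):
    scores, cohort = study
    rep = subgroup_report(scores, cohort)
    by = rep.set_index(["methodology", "column"])
    # combinations without the aneuploidy score keep perfect specificity
    assert by.loc[("signal", "all"), "specificity"] == pytest.approx(100.0)
    assert by.loc[("signal+protein17", "all"), "fp"] == 0
    # any combination including it inherits its two false positives
    for m in ("gas", "signal+gas", "protein17+gas", "signal+protein17+gas"):
        assert by.loc[(m, "all"), "fp"] == 2
        assert by.loc[(m, "all"), "specificity"] == pytest.approx(93.75)
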