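"""Mann-Whitney, Spearman, response ROC and CN-sign stratified rates."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from seroindex.stats import (
    clopper_pearson,
    group_contrast_suite,
    mann_whitney,
    responder_rate_by_cn_sign,
    response_roc,
    spearman,
)

from conftest import make_record


class TestMannWhitney:
    def test_enumeration_example(self):
        # all C(4,2)=6 rank assignments; U=0 or U=4 are the extremes
        result = mann_whitney([1, 2], [3, 4])
        assert result.u_statistic == 0.0
        assert result.p_value == pytest.approx(1 / 3)
        assert result.method == "exact"

    def test_identical_multisets_give_p_one(self):
        result = mann_whitney([1, 2, 3], [1, 2, 3])
        assert result.p_value == pytest.approx(1.0)

    def test_u_identity(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            assert (
                mann_whitney(a, b).u_statistic + mann_whitney(b, a).u_statistic
            ) == pytest.approx(len(a) * len(b))

    def test_exact_matches_scipy_for_all_tiefree_inputs(self):
        """Full agreement with the tie-free exact null up to combined n=8.

        Tie-free p-values depend only on the rank pattern, so enumerating
        every split of ranks 1..N covers every tie-free input.
        """
        for total in range(2, 9):
            ranks = np.arange(1, total + 1, dtype=float)
            for n_a in range(1, total):
                for combo in itertools.combinations(range(total), n_a):
                    mask = np.zeros(total, dtype=bool)
                    mask[list(combo)] = True
                    a, b = ranks[mask], ranks[~mask]
                    expected = sps.mannwhitneyu(
                        a, b, alternative="two-sided", method="exact"
                    ).pvalue
                    assert mann_whitney(a, b).p_value == pytest.approx(
                        float(expected), abs=1e-12
                    ), (a, b)

    def test_asymptotic_branch_uses_corrections(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        result = mann_whitney(a, b)
        assert result.method == "asymptotic"
        expected = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert result.p_value == pytest.approx(float(expected))

    def test_medians_reported(self):
        result = mann_whitney([1, 2, 3], [10, 20, 30, 40])
        assert (result.median_a, result.median_b) == (2.0, 25.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        # rank deviations d = (0,-1,1,-1,1), sum d^2 = 4: 1 - 6*4/(5*24) = 0.8
        result = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert result.rho == pytest.approx(0.8)

    def test_rho_equals_pearson_on_ranks(self, rng):
        for _ in range(30):
            n = int(rng.integers(9, 40))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            expected = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
            assert spearman(x, y).rho == pytest.approx(float(expected), abs=1e-12)

    def test_exact_permutation_p_matches_scipy_permutation_test(self, rng):
        x = rng.normal(size=6)
        y = 0.8 * x + 0.3 * rng.normal(size=6)

        def statistic(perm_y):
            return sps.pearsonr(sps.rankdata(x), sps.rankdata(perm_y)).statistic

        oracle = sps.permutation_test(
            (y,), statistic, permutation_type="pairings",
            alternative="two-sided", n_resamples=np.inf,
        )
        result = spearman(x, y)
        assert result.method == "exact"
        assert result.p_value == pytest.approx(float(oracle.pvalue), abs=1e-12)

    def test_constant_input_flagged(self):
        result = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert result.rho is None and "CONSTANT_INPUT" in result.flags

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestResponseROC:
    def test_perfect_separation(self):
        result = response_roc(
            [0.5, 0.6, 0.7] + [0.1] * 10,
            [True, True, True] + [False] * 10,
            target_specificity=0.99,
        )
        assert result.sensitivity_pct == 100.0
        assert result.specificity_pct == 100.0

    def test_specificity_anchored_threshold(self):
        # at full specificity the threshold sits on the non-responder max;
        # the strict-greater rule keeps every non-responder negative
        responders = [0.5, 0.6, 0.1]
        nonresp = [0.2, 0.3]
        result = response_roc(
            responders + nonresp,
            [True] * 3 + [False] * 2,
            target_specificity=1.0,
        )
        assert result.cutoff_used >= 0.3
        assert result.specificity_pct == 100.0
        assert result.sensitivity_pct == pytest.approx(66.7, abs=0.1)

    def test_fixed_threshold_degenerate(self):
        result = response_roc(
            [0.5, 0.6, 0.7, 0.8],
            [True, True, False, False],
            fixed_threshold=0.0,
        )
        assert result.sensitivity_pct == 100.0
        assert result.specificity_pct == 0.0
        assert result.threshold_source == "fixed"

    def test_full_specificity_threshold_clears_reference(self, rng):
        nonresp = rng.lognormal(-1, 0.5, 40)
        resp = rng.lognormal(0, 0.5, 40)
        values = np.concatenate([resp, nonresp])
        labels = [True] * 40 + [False] * 40
        result = response_roc(values, labels, target_specificity=1 - 1e-9)
        assert result.cutoff_used >= nonresp.max() - 1e-12
        assert result.specificity_pct == 100.0

    def test_direction_flag_flips_scale(self):
        values = [0.1, 0.2, 0.8, 0.9]
        labels = [True, True, False, False]  # responders LOWER here
        result = response_roc(
            values, labels, target_specificity=0.99, higher_in_responders=False
        )
        assert result.sensitivity_pct == 100.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            response_roc([1.0, 2.0], [True, True], target_specificity=0.9)


class TestResponderRateByCNSign:
    @staticmethod
    def _records(neg_responders, neg_total, pos_responders, pos_total):
        records = []
        for i in range(neg_total):
            records.append(
                make_record(
                    f"N{i}", cit=0.1, native=0.5, treatment="mtx",
                    eular_responder_6m=i < neg_responders,
                )
            )
        for i in range(pos_total):
            records.append(
                make_record(
                    f"P{i}", cit=0.9, native=0.2, treatment="mtx",
                    eular_responder_6m=i < pos_responders,
                )
            )
        return records

    def test_counting_example(self):
        rates = responder_rate_by_cn_sign(self._records(7, 8, 3, 10), "mtx")
        by_stratum = {r.stratum: r for r in rates}
        assert by_stratum["negative_delta"].rate_pct == pytest.approx(87.5)
        assert by_stratum["non_negative_delta"].rate_pct == pytest.approx(30.0)

    def test_all_responders_in_negative_stratum(self):
        rates = responder_rate_by_cn_sign(self._records(5, 5, 0, 3), "mtx")
        assert rates[0].rate_pct == 100.0

    def test_strata_counts_partition_treated(self):
        rates = responder_rate_by_cn_sign(self._records(7, 8, 3, 10), "mtx")
        assert sum(r.n for r in rates) == 18

    def test_empty_stratum_missing(self):
        rates = responder_rate_by_cn_sign(self._records(0, 0, 3, 10), "mtx")
        neg = next(r for r in rates if r.stratum == "negative_delta")
        assert neg.n == 0 and neg.rate_pct is None

    def test_clopper_pearson_matches_scipy(self):
        lo, hi = clopper_pearson(7, 8)
        ci = sps.binomtest(7, 8).proportion_ci(confidence_level=0.95, method="exact")
        assert (lo, hi) == (pytest.approx(float(ci.low)), pytest.approx(float(ci.high)))


class TestGroupContrastSuite:
    def test_identical_groups_p_one(self):
        records = [
            make_record(f"A{i}", cit=v, native=v / 2, lung_parenchymal_change=False)
            for i, v in enumerate([0.1, 0.2, 0.3])
        ] + [
            make_record(f"B{i}", cit=v, native=v / 2, lung_parenchymal_change=True)
            for i, v in enumerate([0.1, 0.2, 0.3])
        ]
        comps = group_contrast_suite(records, "lung_pc")
        assert comps and all(c.p_value == pytest.approx(1.0) for c in comps)

    def test_three_se_levels_give_three_contrasts_per_marker(self, rng):
        records = [
            make_record(
                f"S{i}", cit=float(rng.lognormal()), native=float(rng.lognormal()),
                se_copies=int(i % 3),
            )
            for i in range(30)
        ]
        comps = group_contrast_suite(records, "se_copies")
        per_marker = {}
        for c in comps:
            per_marker.setdefault(c.marker, []).append((c.group_a_label, c.group_b_label))
        assert all(len(v) == 3 for v in per_marker.values())

    def test_location_shift_detected(self, rng):
        detected = 0
        n_rep = 50
        for _ in range(n_rep):
            records = [
                make_record(f"A{i}", cit=float(rng.normal(0, 1)), native=0.0,
                            arthritis_progression=False)
                for i in range(200)
            ] + [
                make_record(f"B{i}", cit=float(rng.normal(1, 1)), native=0.0,
                            arthritis_progression=True)
                for i in range(200)
            ]
            comps = group_contrast_suite(records, "progression")
            cit_p = next(c.p_value for c in comps if c.marker == "cit")
            detected += cit_p < 0.001
        assert detected >= 0.95 * n_rep

    def test_small_level_skipped_and_missing_excluded(self, rng, caplog):
        records = [
            make_record(f"S{i}", cit=float(rng.lognormal()), se_copies=0)
            for i in range(10)
        ]
        records.append(make_record("lone", se_copies=2))
        records.append(make_record("missing", se_copies=None))
        comps = group_contrast_suite(records, "se_copies")
        assert comps == []  # the 0-vs-2 contrast is skipped (level n=1)

    def test_bh_column_optional(self, rng):
        records = [
            make_record(f"S{i}", cit=float(rng.lognormal()),
                        native=float(rng.lognormal()),
                        lung_parenchymal_change=bool(i % 2))
            for i in range(40)
        ]
        plain = group_contrast_suite(records, "lung_pc")
        assert all(c.p_adjusted is None for c in plain)
        adjusted = group_contrast_suite(records, "lung_pc", adjust=True)
        assert all(c.p_adjusted is not None for c in adjusted)
        expected = sps.false_discovery_control(
            [c.p_value for c in adjusted], method="bh"
        )
        assert [c.p_adjusted for c in adjusted] == pytest.approx(list(expected))

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            group_contrast_suite([], "age")
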