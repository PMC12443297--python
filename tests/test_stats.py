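"""Tests for the stratified disparity statistics."""

import numpy as np
import pandas as pd
import pytest

from spatialaccess import (
    AccessSurface,
    ConfigurationError,
    IntegrityError,
    ReportConfig,
    disparity_report,
    percent_change,
    rank_sum_test,
    stratum_medians,
    zero_inflated_rank_sum,
)
from spatialaccess.stats import _ranksum_z
from _oracles import oracle_permutation_p, oracle_rank_sum_exact_p
from conftest import make_area


def surface(values, ids=None, mode="composite", classification="primary_care",
            period="2016Q4"):
    ids = ids or [f"A{i}" for i in range(len(values))]
    return AccessSurface(mode, classification, period, pd.Series(values, index=ids))


class TestStratumMedians:
    def test_identical_values_give_zero_differences(self):
        areas = [make_area(f"A{i}", ruca=r)
                 for i, r in enumerate(["metropolitan"] * 3 + ["rural"] * 3)]
        surf = surface([7.0] * 6)
        comp = stratum_medians(surf, areas, "rural_urban_class", "metropolitan")
        assert all(r.median == 7.0 for r in comp.rows)
        assert comp.row("rural").diff_vs_ref == 0.0

    def test_two_strata_hand_example(self):
        areas = [make_area(f"A{i}", ruca="metropolitan") for i in range(3)] + \
                [make_area(f"A{i+3}", ruca="rural") for i in range(3)]
        surf = surface([1, 2, 3, 4, 5, 6])
        comp = stratum_medians(surf, areas, "rural_urban_class", "metropolitan")
        assert comp.row("metropolitan").median == 2.0
        assert comp.row("rural").median == 5.0
        assert comp.row("rural").diff_vs_ref == -3.0  # reference minus stratum

    def test_sign_convention_matches_reference_minus_stratum(self):
        # degenerate single-value strata reproduce a printed-table difference:
        # metropolitan 114.3, micropolitan 72.6 -> difference 41.7
        areas = [make_area("A0", ruca="metropolitan"), make_area("A1", ruca="micropolitan")]
        comp = stratum_medians(surface([114.3, 72.6]), areas,
                               "rural_urban_class", "metropolitan")
        assert comp.row("micropolitan").diff_vs_ref == pytest.approx(41.7)

    def test_empty_stratum_omitted_with_warning(self, caplog):
        areas = [make_area("A0", ruca="metropolitan"), make_area("A1", ruca="")]
        with caplog.at_level("WARNING"):
            comp = stratum_medians(surface([1.0, 2.0]), areas,
                                   "rural_urban_class", "metropolitan")
        assert {r.stratum for r in comp.rows} == {"metropolitan", ""}

    def test_missing_reference_is_error(self):
        areas = [make_area("A0", ruca="rural")]
        with pytest.raises(IntegrityError):
            stratum_medians(surface([1.0]), areas, "rural_urban_class", "metropolitan")


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        res = rank_sum_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p_value > 0.95

    def test_extreme_separation_small_n_exact(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "rank-sum-exact"
        assert res.p_value == pytest.approx(0.1)  # 2 of 20 orderings

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n1, n2 = rng.integers(2, 5), rng.integers(2, 5)
            pooled = rng.choice(100, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            assert rank_sum_test(x, y).p_value == pytest.approx(
                oracle_rank_sum_exact_p(x, y), abs=1e-12)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1.5, 1, 200)
        res = rank_sum_test(x, y)
        assert res.method == "rank-sum-normal"
        assert res.p_value < 0.001
        perm = oracle_permutation_p(x, y, lambda a, b: _ranksum_z(a, b), 999,
                                    np.random.default_rng(2))
        assert perm < 0.005  # oracle agrees the shift is real

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        assert rank_sum_test(x, y).p_value == pytest.approx(rank_sum_test(y, x).p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            rank_sum_test([], [1.0])


class TestZeroInflatedRankSum:
    def test_all_zero_both_groups_degenerate_p_one(self):
        res = zero_inflated_rank_sum([0, 0, 0], [0, 0, 0, 0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_identical_samples_near_one(self):
        x = [0, 0, 0, 1.0, 2.0, 3.0]
        res = zero_inflated_rank_sum(x, list(x))
        assert res.p_value > 0.95

    def test_separated_semicontinuous_samples(self):
        rng = np.random.default_rng(4)
        n = 200
        x = np.where(rng.uniform(size=n) < 0.8, 0.0, rng.lognormal(-1, 0.3, n))
        y = np.where(rng.uniform(size=n) < 0.1, 0.0, rng.lognormal(1.5, 0.3, n))
        two_part = zero_inflated_rank_sum(x, y)
        naive = rank_sum_test(x, y)
        assert two_part.p_value < 0.001
        assert two_part.p_value <= naive.p_value

    def test_no_zeros_reduces_to_positive_part_only(self):
        res = zero_inflated_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.df == 1

    def test_null_calibration_quick(self):
        # smoke-level calibration; the full 10,000-replicate check runs in the
        # acceptance suite
        rng = np.random.default_rng(5)
        rej = 0
        reps = 500
        for _ in range(reps):
            def draw():
                z = rng.uniform(size=60) < 0.6
                v = rng.lognormal(0, 1, size=60)
                v[z] = 0.0
                return v
            rej += zero_inflated_rank_sum(draw(), draw()).p_value < 0.05
        assert 0.02 <= rej / reps <= 0.09


class TestPercentChange:
    def test_basic_arithmetic(self):
        pc = percent_change(surface([100.0]), surface([115.0], period="2019Q4"))
        assert pc.values.iloc[0] == pytest.approx(15.0)

    def test_zero_to_zero_is_zero(self):
        pc = percent_change(surface([0.0]), surface([0.0], period="2019Q4"))
        assert pc.values.iloc[0] == 0.0
        assert pc.n_undefined == 0

    def test_zero_to_positive_is_undefined_and_counted(self):
        pc = percent_change(surface([0.0, 50.0]), surface([5.0, 60.0], period="2019Q4"))
        assert np.isnan(pc.values.iloc[0])
        assert pc.undefined_ids == ["A0"]
        assert pc.defined.tolist() == [pytest.approx(20.0)]

    def test_scale_free(self):
        v1, v2 = [10.0, 20.0, 0.0], [12.0, 15.0, 0.0]
        a = percent_change(surface(v1), surface(v2, period="2019Q4")).values
        b = percent_change(surface([3 * v for v in v1]),
                           surface([3 * v for v in v2], period="2019Q4")).values
        assert a.tolist() == b.tolist()

    def test_mismatched_area_sets_rejected(self):
        with pytest.raises(IntegrityError):
            percent_change(surface([1.0], ids=["A0"]),
                           surface([1.0], ids=["B0"], period="2019Q4"))


class TestDisparityReport:
    def _areas(self, n_metro=20, n_rural=20):
        return ([make_area(f"M{i}", ruca="metropolitan", adi=f"Q{1 + i % 4}")
                 for i in range(n_metro)] +
                [make_area(f"R{i}", ruca="rural", adi=f"Q{1 + i % 4}")
                 for i in range(n_rural)])

    def test_no_providers_all_medians_zero_p_one(self):
        areas = self._areas()
        ids = [a.area_id for a in areas]
        zeros = {p: surface([0.0] * len(ids), ids=ids, period=p)
                 for p in ("2016Q4", "2019Q4")}
        blocks = disparity_report(zeros, areas)
        for block in blocks:
            for row in block.rows:
                assert row.median == 0.0
                if row.p_value is not None:
                    assert row.p_value == 1.0

    def test_reference_rows_carry_no_test(self):
        areas = self._areas()
        ids = [a.area_id for a in areas]
        rng = np.random.default_rng(6)
        surf = {p: surface(rng.uniform(0, 100, len(ids)), ids=ids, period=p)
                for p in ("2016Q4", "2019Q4")}
        blocks = disparity_report(surf, areas)
        assert {b.metric for b in blocks} == {"access", "percent_change"}
        for block in blocks:
            ref = block.row(block.reference)
            assert ref.diff_vs_ref is None and ref.p_value is None

    def test_zero_excess_switches_test_choice(self):
        areas = self._areas()
        ids = [a.area_id for a in areas]
        rng = np.random.default_rng(7)
        metro_vals = rng.uniform(50, 100, 20)
        rural_vals = np.where(rng.uniform(size=20) < 0.6, 0.0, rng.uniform(0, 10, 20))
        surf = {"2016Q4": surface(np.concatenate([metro_vals, rural_vals]), ids=ids)}
        blocks = disparity_report(surf, areas, ReportConfig(change_periods=None))
        ruca = next(b for b in blocks if b.stratum_variable == "rural_urban_class")
        assert ruca.row("rural").test == "zero-inflated-rank-sum"
        assert ruca.row("rural").p_value < 0.05
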