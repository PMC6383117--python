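"""Percentile thresholding and the scenario rule engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropshift import (
    CATEGORY_CODES,
    MAJOR_CHANGE,
    NO_CHANGE,
    SCENARIOS,
    ScenarioRuleSet,
    classify_transitions,
    percentile_threshold,
)
from conftest import make_mask, make_suitability
from oracles import classify_grid, percentile_linear

CODE_TO_NAME = {v: k for k, v in CATEGORY_CODES.items()}


class TestPercentileThreshold:
    def test_single_element_pool_returns_it(self):
        lst = make_suitability([[0.42, 0.9], [0.1, 0.3]])
        mask = make_mask([[0.5, 0.0], [0.0, 0.0]])
        for p in (0, 33, 50, 67, 100):
            assert percentile_threshold(lst, mask, p) == 0.42

    def test_endpoints_are_min_and_max(self, rng):
        vals = rng.uniform(size=(6, 6))
        lst = make_suitability(vals)
        mask = make_mask(np.full((6, 6), 0.5))
        assert percentile_threshold(lst, mask, 0) == vals.min()
        assert percentile_threshold(lst, mask, 100) == vals.max()

    def test_three_value_pool_matches_oracle(self):
        lst = make_suitability([[0.2, 0.4, 0.6]])
        mask = make_mask([[1.0, 1.0, 1.0]])
        got = percentile_threshold(lst, mask, 33)
        assert got == pytest.approx(percentile_linear([0.2, 0.4, 0.6], 33))

    @pytest.mark.parametrize("p", [0, 33, 50, 67, 100])
    def test_random_pools_match_sort_and_interpolate_oracle(self, rng, p):
        for size in (1, 2, 5, 40, 400):
            vals = rng.uniform(size=size)
            lst = make_suitability(vals.reshape(1, size))
            mask = make_mask(np.full((1, size), 0.9))
            got = percentile_threshold(lst, mask, p)
            assert got == pytest.approx(percentile_linear(vals, p), abs=1e-12)

    def test_pool_excludes_notused_and_missing(self):
        lst = make_suitability([[0.1, 0.9, np.nan, 0.5]])
        mask = make_mask([[0.5, 0.005, 0.5, 0.5]])
        # pool = {0.1, 0.5}: cell 2 is not used, cell 3 missing in LSt
        assert percentile_threshold(lst, mask, 100) == 0.5

    def test_empty_used_pool_is_an_error(self):
        lst = make_suitability([[0.1, 0.9]])
        mask = make_mask([[0.0, 0.0]])
        with pytest.raises(ValueError, match="addition rule|undefined"):
            percentile_threshold(lst, mask, 33)


def random_inputs(rng, shape, missing_prob=0.0):
    lst_vals = rng.uniform(size=shape)
    lsf_vals = rng.uniform(size=shape)
    frac = np.where(rng.random(shape) < 0.4, rng.uniform(0.01, 1.0, shape), 0.0)
    if missing_prob:
        for arr in (lst_vals, lsf_vals, frac):
            arr[rng.random(shape) < missing_prob] = np.nan
    # keep at least one used, non-missing cell so the threshold exists
    lst_vals[0, 0], lsf_vals[0, 0], frac[0, 0] = 0.5, 0.5, 0.5
    lst = make_suitability(lst_vals)
    lsf = make_suitability(lsf_vals, spec=lst.grid, period="future")
    mask = make_mask(frac, spec=lst.grid)
    return lst, lsf, mask


class TestClassifyTransitions:
    def test_used_cell_retained_under_no_change(self):
        # LSt=0.5, LSf=0.6: 0.6 > 0.45 -> unaltered_used
        lst = make_suitability([[0.5]])
        lsf = make_suitability([[0.6]], spec=lst.grid, period="future")
        mask = make_mask([[0.8]], spec=lst.grid)
        t = classify_transitions(lst, lsf, mask, NO_CHANGE)
        assert CODE_TO_NAME[t.codes[0, 0]] == "unaltered_used"

    def test_used_cell_abandoned_under_major_change_below_ten_percent_gain(self):
        # LSt=0.5, LSf=0.54: 0.54 <= 0.55 -> abandoned
        lst = make_suitability([[0.5]])
        lsf = make_suitability([[0.54]], spec=lst.grid, period="future")
        mask = make_mask([[0.8]], spec=lst.grid)
        t = classify_transitions(lst, lsf, mask, MAJOR_CHANGE)
        assert CODE_TO_NAME[t.codes[0, 0]] == "abandoned"

    def test_notused_cell_at_exact_threshold_stays_notused(self):
        # strict ">": LSf equal to the threshold is not added
        lst = make_suitability([[0.4, 0.2]])
        lsf = make_suitability([[0.4, 0.4]], spec=lst.grid, period="future")
        mask = make_mask([[0.5, 0.0]], spec=lst.grid)
        t = classify_transitions(lst, lsf, mask, NO_CHANGE)
        assert t.threshold_used == 0.4  # single used cell pool
        assert CODE_TO_NAME[t.codes[0, 1]] == "unaltered_notused"

    @pytest.mark.parametrize("scenario", ["no_change", "major_change"])
    def test_random_grids_match_cell_by_cell_oracle(self, rng, scenario):
        rules = SCENARIOS[scenario]
        for trial in range(20):
            lst, lsf, mask = random_inputs(rng, (6, 6), missing_prob=0.1)
            t = classify_transitions(lst, lsf, mask, rules)
            expected, thr = classify_grid(
                lst.values, lsf.values, mask.fraction,
                rules.retention_factor, rules.addition_percentile,
            )
            assert t.threshold_used == pytest.approx(thr, abs=1e-12)
            got = np.vectorize(CODE_TO_NAME.get)(t.codes)
            np.testing.assert_array_equal(got, expected)

    def test_partition_and_permitted_categories(self, rng):
        lst, lsf, mask = random_inputs(rng, (12, 12), missing_prob=0.15)
        t = classify_transitions(lst, lsf, mask, NO_CHANGE)
        missing = (np.isnan(lst.values) | np.isnan(lsf.values)
                   | np.isnan(mask.fraction))
        assert np.array_equal(t.codes == 255, missing)
        used = mask.used & ~missing
        used_codes = set(np.unique(t.codes[used]).tolist())
        assert used_codes <= {CATEGORY_CODES["unaltered_used"], CATEGORY_CODES["abandoned"]}
        notused_codes = set(np.unique(t.codes[~used & ~missing]).tolist())
        assert notused_codes <= {CATEGORY_CODES["added"], CATEGORY_CODES["unaltered_notused"]}

    def test_scenario_nesting(self, rng):
        for trial in range(10):
            lst, lsf, mask = random_inputs(rng, (15, 15))
            t_no = classify_transitions(lst, lsf, mask, NO_CHANGE)
            t_ma = classify_transitions(lst, lsf, mask, MAJOR_CHANGE)
            ab_no = t_no.category_mask("abandoned")
            ab_ma = t_ma.category_mask("abandoned")
            assert np.all(ab_ma[ab_no])  # abandoned(no) subset of abandoned(major)
            add_no = t_no.category_mask("added")
            add_ma = t_ma.category_mask("added")
            assert np.all(add_no[add_ma])  # added(major) subset of added(no)

    def test_identity_climate_edge(self, rng):
        lst, _, mask = random_inputs(rng, (10, 10))
        lst.values[2, :5] = 0.0  # force some zero-suitability used cells
        lsf = make_suitability(lst.values.copy(), spec=lst.grid, period="future")
        t_no = classify_transitions(lst, lsf, mask, NO_CHANGE)
        # no_change abandons exactly the used cells with LSt == 0
        expected = mask.used & (lst.values == 0.0)
        np.testing.assert_array_equal(t_no.category_mask("abandoned"), expected)
        # major_change abandons every used cell: LSf > 1.1*LSt never holds
        t_ma = classify_transitions(lst, lsf, mask, MAJOR_CHANGE)
        np.testing.assert_array_equal(t_ma.category_mask("abandoned"), mask.used)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20)
    def test_raising_lsf_moves_toward_used_or_added(self, seed):
        rng = np.random.default_rng(seed)
        lst, lsf, mask = random_inputs(rng, (5, 5))
        t0 = classify_transitions(lst, lsf, mask, NO_CHANGE)
        bumped = np.clip(lsf.values + 0.2, 0, 1)
        lsf2 = make_suitability(bumped, spec=lsf.grid, period="future")
        t1 = classify_transitions(lst, lsf2, mask, NO_CHANGE)
        # abandoned can only become unaltered_used, notused only added
        lost_used = t0.category_mask("unaltered_used") & ~t1.category_mask("unaltered_used")
        assert not lost_used.any()
        lost_added = t0.category_mask("added") & ~t1.category_mask("added")
        assert not lost_added.any()

    def test_threshold_independent_of_future_suitability(self, rng):
        lst, lsf, mask = random_inputs(rng, (8, 8))
        t0 = classify_transitions(lst, lsf, mask, NO_CHANGE)
        other = make_suitability(rng.uniform(size=(8, 8)), spec=lst.grid, period="future")
        t1 = classify_transitions(lst, other, mask, NO_CHANGE)
        assert t0.threshold_used == t1.threshold_used

    def test_grid_mismatch_reports_both_shapes(self, rng):
        lst, lsf, mask = random_inputs(rng, (4, 4))
        other = make_suitability(np.zeros((5, 5)), period="future")
        with pytest.raises(ValueError, match=r"\(4, 4\).*\(5, 5\)|mismatch"):
            classify_transitions(lst, other, mask, NO_CHANGE)

    def test_rule_set_constants(self):
        assert NO_CHANGE.retention_factor == 0.9
        assert NO_CHANGE.addition_percentile == 33.0
        assert MAJOR_CHANGE.retention_factor == 1.1
        assert MAJOR_CHANGE.addition_percentile == 67.0
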