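import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingquant import (
    DegenerateGroupsError,
    ValidationError,
    compare_all,
    comparisons_frame,
    star_annotation,
    t_test,
)
from wingquant.quantify import QuantRecord

from _oracles import pooled_t_formula


def _record(genotype, index, i=0):
    return QuantRecord(
        image_id=f"{genotype}_{i}",
        genotype=genotype,
        disc_area_px=10000,
        gfp_area_px=int(index * 10000),
        gfp_area_unrestricted_px=int(index * 10000),
        proliferation_index=index,
        threshold_used=0.5,
        params_fingerprint="abc",
    )


def _records(genotype, values):
    return [_record(genotype, v, i) for i, v in enumerate(values)]


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        c = t_test([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert c.t_stat == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)

    def test_matches_textbook_pooled_formula(self):
        c = t_test([1, 2, 3], [4, 5, 6], "student_pooled")
        t, df, p = pooled_t_formula([1, 2, 3], [4, 5, 6])
        assert c.t_stat == pytest.approx(t, abs=1e-12)
        assert c.df == df == 4
        assert c.p_value == pytest.approx(p, abs=1e-12)
        # frozen values from the closed form: t = -3/sqrt(2/3)
        assert c.t_stat == pytest.approx(-3.6742346141747673, abs=1e-10)
        assert c.p_value == pytest.approx(0.021311641128756727, abs=1e-10)

    def test_swapping_groups_flips_t_keeps_p(self, rng):
        a, b = rng.normal(0.2, 0.05, 10), rng.normal(0.3, 0.05, 12)
        c1, c2 = t_test(a, b), t_test(b, a)
        assert c1.t_stat == pytest.approx(-c2.t_stat)
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            t_test([0.1], [0.2, 0.3])

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.raises(DegenerateGroupsError):
            t_test([0.2, 0.2], [0.4, 0.4])

    def test_pooled_df_convention(self, rng):
        c = t_test(rng.normal(size=7), rng.normal(size=9), "student_pooled")
        assert c.df == 14

    def test_welch_df_below_pooled_for_unequal_variances(self, rng):
        a = rng.normal(0, 0.01, 6)
        b = rng.normal(0, 1.0, 20)
        c = t_test(a, b, "welch")
        assert c.variant == "welch"
        assert c.df < a.size + b.size - 2

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_pooled_matches_formula_on_random_groups(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), rng.integers(2, 30))
        b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), rng.integers(2, 30))
        c = t_test(a, b, "student_pooled")
        t, df, p = pooled_t_formula(a, b)
        assert c.t_stat == pytest.approx(t, abs=1e-10)
        assert c.p_value == pytest.approx(p, abs=1e-10)
        assert c.df == df

    @given(st.floats(-5, 5), st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_p_invariant_under_affine_shift_and_scale(self, shift, scale):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0.2, 0.05, 8), rng.normal(0.35, 0.05, 8)
        base = t_test(a, b).p_value
        assert t_test(a + shift, b + shift).p_value == pytest.approx(base, rel=1e-9)
        assert t_test(a * scale, b * scale).p_value == pytest.approx(base, rel=1e-9)


class TestStarAnnotation:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.0005, "***"),
            (0.005, "**"),
            (0.03, "*"),
            (0.2, ""),
            (0.001, "**"),  # strict boundary: not promoted to ***
            (0.01, "*"),
            (0.05, ""),
        ],
    )
    def test_printed_thresholds_with_strict_boundaries(self, p, stars):
        assert star_annotation(p) == stars

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            star_annotation(1.2)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_non_increasing_step_function(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert len(star_annotation(hi)) <= len(star_annotation(lo))


class TestCompareAll:
    def test_counting_against_two_references(self, rng):
        records = (
            _records("ctrl", rng.normal(0.1, 0.02, 5))
            + _records("p35", rng.normal(0.12, 0.02, 5))
            + _records("mutant", rng.normal(0.3, 0.02, 5))
        )
        comps = compare_all(records, ["ctrl", "p35"])
        # each reference is compared to every other genotype, never itself
        assert len(comps) == 4
        pairs = {(c.group_a, c.group_b) for c in comps}
        assert pairs == {
            ("p35", "ctrl"),
            ("mutant", "ctrl"),
            ("ctrl", "p35"),
            ("mutant", "p35"),
        }

    def test_missing_reference_label_errors(self, rng):
        records = _records("a", rng.normal(0.1, 0.02, 4))
        with pytest.raises(ValidationError, match="ghost"):
            compare_all(records, ["ghost"])

    def test_large_effect_is_flagged_significant(self, rng):
        a = rng.normal(0.10, 0.03, 15)
        b = rng.normal(0.25, 0.03, 15)
        records = _records("ctrl", a) + _records("over", b)
        (comp,) = compare_all(records, ["ctrl"])
        assert comp.p_value < 0.05
        assert comp.stars != ""

    def test_frame_renders_ns_as_empty_string(self, rng):
        vals = rng.normal(0.2, 0.05, 6)
        records = _records("a", vals) + _records("b", vals + rng.normal(0, 1e-4, 6))
        frame = comparisons_frame(compare_all(records, ["a"]))
        assert frame.loc[0, "stars"] == ""
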