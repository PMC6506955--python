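"""Group statistics: t-test against a hand-coded oracle, Bonferroni rule,
two-way ANOVA behavior, ECDF properties and per-animal pooling."""

import math

import numpy as np
import pandas as pd
import pytest

from periplaque.config import RunConfig
from periplaque.errors import InsufficientDataError, ValidationError
from periplaque.stats import (
    ImageMeasurements,
    bonferroni,
    compare_class_fractions,
    compare_groups,
    cumulative_distribution,
    significance_stars,
    summarize_mouse,
)


def student_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test, coded independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.special import stdtr

    df = na + nb - 2
    p = 2 * (1 - stdtr(df, abs(t)))
    return t, p


def frame(groups):
    rows = []
    for cond, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"animal_id": f"{cond}{i}", "condition": cond, "metric": v})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_matches_hand_coded_student_t(self):
        a, b = [2.1, 2.5, 1.9, 2.3], [1.1, 1.4, 1.0]
        res = compare_groups(frame({"A": a, "B": b}), "metric")
        t, p = student_t_oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.group_means == (pytest.approx(np.mean(a)), pytest.approx(np.mean(b)))

    def test_identical_groups_p_one(self):
        res = compare_groups(frame({"A": [1, 2, 3], "B": [1, 2, 3]}), "metric")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_variance_separation_degenerate(self):
        res = compare_groups(frame({"A": [0, 0, 0, 0], "B": [10, 10, 10, 10]}), "metric")
        assert res.p_value == 0.0
        assert res.degenerate

    def test_group_swap_symmetry(self):
        df = frame({"A": [5.0, 6.0, 7.0], "B": [1.0, 2.0, 3.0]})
        res = compare_groups(df, "metric")
        swapped = df.copy()
        swapped["condition"] = swapped["condition"].map({"A": "B", "B": "A"})
        res2 = compare_groups(swapped, "metric")
        assert res2.statistic == pytest.approx(-res.statistic)
        assert res2.p_value == pytest.approx(res.p_value)

    def test_welch_option_differs_under_unequal_variance(self):
        df = frame({"A": [1.0, 1.1, 0.9, 1.0], "B": [2.0, 6.0, 4.0]})
        student = compare_groups(df, "metric", equal_var=True)
        welch = compare_groups(df, "metric", equal_var=False)
        assert student.p_value != welch.p_value
        assert welch.test_name == "Welch t"

    def test_insufficient_animals_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups(frame({"A": [1.0], "B": [1.0, 2.0]}), "metric")

    def test_stars_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == "ns"


class TestBonferroni:
    def test_multiplication_rule(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)

    def test_capped_at_one(self):
        assert bonferroni(0.5, 4) == 1.0

    def test_identity_for_single_test(self):
        assert bonferroni(0.123, 1) == 0.123


class TestCompareClassFractions:
    def _summaries(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cond, delta in (("WT", 0.0), ("KO", shift)):
            for i in range(6):
                dense = np.clip(0.5 - delta + rng.normal(0, 0.03), 0, 1)
                fib = np.clip(0.3 + delta + rng.normal(0, 0.03), 0, 1)
                mixed = max(0.0, 1 - dense - fib)
                rows.append(
                    {
                        "animal_id": f"{cond}{i}",
                        "condition": cond,
                        "frac_dense_core": dense,
                        "frac_fibrillar": fib,
                        "frac_mixed": mixed,
                    }
                )
        return pd.DataFrame(rows)

    def test_null_adjusted_p_bounded_below_by_unadjusted(self):
        anova, results = compare_class_fractions(self._summaries(0.0))
        for r in results:
            assert r.p_adjusted >= r.p_value
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_value))

    def test_planted_shift_detected_in_shifted_classes(self):
        anova, results = compare_class_fractions(self._summaries(0.2, seed=3))
        by_metric = {r.metric: r for r in results}
        assert by_metric["frac_dense_core"].p_adjusted < 0.05
        assert by_metric["frac_fibrillar"].p_adjusted < 0.05
        # condition × class interaction carries the shift
        assert anova.loc["C(condition):C(plaque_class)", "PR(>F)"] < 0.05

    def test_absent_class_excluded_with_warning(self):
        df = self._summaries(0.0)
        df["frac_mixed"] = 0.0
        with pytest.warns(UserWarning, match="mixed"):
            _, results = compare_class_fractions(df)
        assert {r.metric for r in results} == {"frac_dense_core", "frac_fibrillar"}


class TestCumulativeDistribution:
    def test_single_value(self):
        df = cumulative_distribution([5.0])
        assert list(df.value) == [5.0] and list(df.ecdf) == [1.0]

    def test_step_heights(self):
        df = cumulative_distribution([3, 1, 4, 2])
        assert list(df.value) == [1, 2, 3, 4]
        assert list(df.ecdf) == [0.25, 0.5, 0.75, 1.0]

    def test_nondecreasing_to_one(self):
        rng = np.random.default_rng(0)
        df = cumulative_distribution(rng.normal(size=57))
        assert (np.diff(df.ecdf) >= 0).all()
        assert df.ecdf.iloc[-1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_distribution([])


def image(animal, areas, area_mm2=0.5, classes=None, **extra):
    n = len(areas)
    plaques = pd.DataFrame(
        {
            "label": range(1, n + 1),
            "area_um2": areas,
            "plaque_class": classes or ["dense_core"] * n,
            "on_border": [False] * n,
        }
    )
    for k, v in extra.pop("plaque_cols", {}).items():
        plaques[k] = v
    neurons = extra.pop("neurons", pd.DataFrame(columns=["puncta_count", "distance_to_nearest_plaque_um"]))
    return ImageMeasurements(
        image_id=f"{animal}_img",
        animal_id=animal,
        condition="WT",
        area_mm2=area_mm2,
        plaques=plaques,
        neurons=neurons,
        **extra,
    )


class TestSummarizeMouse:
    def test_mean_size_pooled(self, config):
        s = summarize_mouse([image("m1", [100.0, 200.0])], config)
        assert s.mean_plaque_size_um2 == 150.0
        assert s.n_plaques_analyzed == 2

    def test_density_pools_area(self, config):
        s = summarize_mouse([image("m1", [100.0] * 3), image("m1", [100.0] * 7)], config)
        assert s.plaque_density_per_mm2 == pytest.approx(10.0 / 1.0)

    def test_neuron_fraction_uses_search_radius(self, config):
        neurons = pd.DataFrame(
            {"puncta_count": [4, 0, 9], "distance_to_nearest_plaque_um": [10.0, 20.0, 500.0]}
        )
        s = summarize_mouse([image("m1", [100.0], neurons=neurons)], config)
        assert s.fraction_abeta_positive_neurons == 0.5

    def test_zero_plaques_missing_fields(self, config):
        s = summarize_mouse([image("m1", [])], config)
        assert math.isnan(s.mean_plaque_size_um2)
        assert s.amyloid_load == 0.0
        assert s.below_min_plaques

    def test_min_plaque_flag(self, config):
        s = summarize_mouse([image("m1", [100.0] * 12)], config)
        assert not s.below_min_plaques
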