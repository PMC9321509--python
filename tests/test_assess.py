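"""Sensitivity and service-importance formulas, grading, superposition."""

import numpy as np
import pytest

from ecosecurity.assess import (
    GradedFactor, SensitivityLayers, ServiceLayers, biodiversity_service,
    composite_importance, composite_sensitivity, grade_factor,
    grade_soil_texture, rainfall_erosivity, slope_degrees, soil_conservation,
    sse, sswl, sld, superpose_environment, water_retention,
)
from conftest import make_grid


def graded(values, name="R"):
    return GradedFactor(make_grid(values), name)


# ---------------------------------------------------------------------------
# Rainfall erosivity


def test_rainfall_erosivity_hand_values():
    flat100 = [make_grid([[100.0]]) for _ in range(12)]
    assert rainfall_erosivity(flat100).values[0, 0] == pytest.approx(333.8424)
    flat0 = [make_grid([[0.0]]) for _ in range(12)]
    assert rainfall_erosivity(flat0).values[0, 0] == pytest.approx(-31.6776)


def test_rainfall_erosivity_is_affine_in_rainfall(rng):
    months = [make_grid(rng.uniform(0, 300, (3, 3))) for _ in range(12)]
    base = rainfall_erosivity(months)
    doubled = rainfall_erosivity([m.copy(2 * m.values) for m in months])
    total = sum(m.values for m in months)
    np.testing.assert_allclose(doubled.values - base.values, 0.3046 * total)


def test_rainfall_erosivity_needs_12_months():
    with pytest.raises(ValueError, match="12"):
        rainfall_erosivity([make_grid([[1.0]])] * 11)


# ---------------------------------------------------------------------------
# Factor grading


@pytest.mark.parametrize("factor,value,grade", [
    ("R", 550.0, 3), ("R", 500.0, 1), ("R", 532.0, 1), ("R", 620.0, 9),
    ("LS", 300.0, 9), ("LS", 70.0, 1), ("LS", 150.0, 5),
    ("C", 0.96, 1), ("C", 0.90, 3), ("C", 0.50, 9), ("C", 0.95, 3),
    ("I", 0.60, 3), ("I", 0.90, 9),
    ("W", 90.0, 1), ("W", 200.0, 7), ("W", 260.0, 9),
])
def test_continuous_factor_bands(factor, value, grade):
    out = grade_factor(make_grid([[value]]), factor)
    assert out.grid.values[0, 0] == grade


def test_soil_texture_grading_and_unknown_code():
    out = grade_soil_texture(make_grid([[6.0, 11.0, 9.0, 13.0, 14.0]]))
    np.testing.assert_array_equal(out.grid.values, [[1, 3, 5, 7, 9]])
    with pytest.raises(ValueError, match="99"):
        grade_soil_texture(make_grid([[99.0]]))


def test_graded_factor_rejects_off_scale_values():
    with pytest.raises(ValueError, match="off-scale"):
        GradedFactor(make_grid([[2.0]]), "R")


def test_grading_propagates_nodata():
    out = grade_factor(make_grid([[550.0, np.nan]]), "R")
    assert out.grid.values[0, 0] == 3 and np.isnan(out.grid.values[0, 1])


# ---------------------------------------------------------------------------
# Sensitivity indices


def test_sswl_hand_values():
    ones = sswl(graded([[1.0]]), graded([[1.0]]), graded([[1.0]]), graded([[1.0]]))
    assert ones.values[0, 0] == 1.0
    nines = sswl(graded([[9.0]]), graded([[9.0]]), graded([[9.0]]), graded([[9.0]]))
    assert nines.values[0, 0] == pytest.approx(9.0)
    mix = sswl(graded([[1.0]]), graded([[3.0]]), graded([[5.0]]), graded([[7.0]]))
    assert mix.values[0, 0] == pytest.approx(105 ** 0.25, abs=1e-4)


def test_sse_is_arithmetic_mean(rng):
    grids = [graded(np.random.default_rng(i).choice([1, 3, 5, 7, 9], (4, 4)))
             for i in range(4)]
    out = sse(*grids)
    expected = sum(g.grid.values for g in grids) / 4
    np.testing.assert_allclose(out.values, expected)
    assert sse(graded([[1.0]]), graded([[3.0]]), graded([[5.0]]),
               graded([[7.0]])).values[0, 0] == 4.0


def test_sld_hand_values():
    eq = sld(graded([[3.0]]), graded([[3.0]]), graded([[3.0]]), graded([[3.0]]))
    assert eq.values[0, 0] == pytest.approx(3.0)
    mix = sld(graded([[9.0]]), graded([[7.0]]), graded([[5.0]]), graded([[3.0]]))
    assert mix.values[0, 0] == pytest.approx(945 ** 0.25, abs=1e-4)


def test_geometric_indices_bounded_and_am_gm(rng):
    grids = [graded(rng.choice([1, 3, 5, 7, 9], (6, 6)).astype(float))
             for _ in range(4)]
    geo = sswl(*grids)
    ari = sse(*grids)
    stack = np.stack([g.grid.values for g in grids])
    assert (geo.values >= stack.min(axis=0) - 1e-12).all()
    assert (geo.values <= stack.max(axis=0) + 1e-12).all()
    assert (geo.values >= 1.0 - 1e-12).all() and (geo.values <= 9.0 + 1e-12).all()
    # AM-GM: the arithmetic mean dominates the geometric mean cellwise
    assert (ari.values >= geo.values - 1e-12).all()


def test_composite_sensitivity_printed_weights():
    layers = SensitivityLayers(sswl=make_grid([[9.0]]), sse=make_grid([[1.0]]),
                               sld=make_grid([[1.0]]))
    out = composite_sensitivity(layers)
    assert out.values[0, 0] == pytest.approx(0.43 * 9 + 0.39 + 0.18)  # 4.44


def test_composite_is_convex_combination(rng):
    a, b, c = (make_grid(rng.uniform(1, 9, (5, 5))) for _ in range(3))
    out = composite_sensitivity(SensitivityLayers(sswl=a, sse=b, sld=c))
    stack = np.stack([a.values, b.values, c.values])
    assert (out.values <= stack.max(axis=0) + 1e-12).all()
    assert (out.values >= stack.min(axis=0) - 1e-12).all()
    same = composite_sensitivity(SensitivityLayers(sswl=a, sse=a, sld=a))
    np.testing.assert_allclose(same.values, a.values)


def test_nonunit_weight_sum_warns_but_runs(caplog):
    layers = SensitivityLayers(sswl=make_grid([[2.0]]), sse=make_grid([[2.0]]),
                               sld=make_grid([[2.0]]), weights=(0.5, 0.5, 0.5))
    with caplog.at_level("WARNING"):
        out = composite_sensitivity(layers)
    assert out.values[0, 0] == pytest.approx(3.0)
    assert "sum" in caplog.text


# ---------------------------------------------------------------------------
# Service indices


def test_water_retention_hand_values():
    wr = water_retention(make_grid([[0.5]]), make_grid([[6 / 13]]),
                         make_grid([[0.8]]), make_grid([[0.25]]))
    assert wr.values[0, 0] == pytest.approx(0.13846, abs=1e-5)
    zero = water_retention(make_grid([[0.0]]), make_grid([[1.0]]),
                           make_grid([[1.0]]), make_grid([[0.0]]))
    assert zero.values[0, 0] == 0.0
    unit = water_retention(make_grid([[1.0]]), make_grid([[1.0]]),
                           make_grid([[1.0]]), make_grid([[0.0]]))
    assert unit.values[0, 0] == 1.0


def test_soil_conservation_hand_values():
    s = soil_conservation(make_grid([[0.6]]), make_grid([[0.3]]), make_grid([[0.2]]))
    assert s.values[0, 0] == pytest.approx(0.336)
    assert soil_conservation(make_grid([[0.9]]), make_grid([[1.0]]),
                             make_grid([[0.1]])).values[0, 0] == 0.0


def test_biodiversity_hand_values():
    s = biodiversity_service(*(make_grid([[0.5]]) for _ in range(4)))
    assert s.values[0, 0] == pytest.approx(0.0625)
    top = biodiversity_service(make_grid([[1.0]]), make_grid([[1.0]]),
                               make_grid([[1.0]]), make_grid([[0.0]]))
    assert top.values[0, 0] == 1.0
    peak = biodiversity_service(make_grid([[1.0]]), make_grid([[1.0]]),
                                make_grid([[1.0]]), make_grid([[1.0]]))
    assert peak.values[0, 0] == 0.0  # highest cell contributes nothing


def test_service_inputs_must_be_normalized():
    with pytest.raises(ValueError, match="normalized"):
        water_retention(make_grid([[1.5]]), make_grid([[0.5]]),
                        make_grid([[0.5]]), make_grid([[0.5]]))


def test_service_indices_stay_in_unit_interval(rng):
    grids = [make_grid(rng.uniform(0, 1, (5, 5))) for _ in range(4)]
    for out in (water_retention(*grids),
                soil_conservation(grids[0], grids[1], grids[2]),
                biodiversity_service(*grids)):
        assert (out.values >= 0).all() and (out.values <= 1).all()


def test_composite_importance_weights():
    layers = ServiceLayers(wr=make_grid([[1.0]]), spro=make_grid([[0.0]]),
                           sbio=make_grid([[0.0]]))
    assert composite_importance(layers).values[0, 0] == pytest.approx(0.45)


# ---------------------------------------------------------------------------
# Superposition


def test_superpose_identical_layers_reproduces_classes(rng):
    vals = rng.uniform(0, 10, (12, 12))
    sens = make_grid(vals)
    imp = make_grid(vals.copy())
    out = superpose_environment(sens, imp)
    np.testing.assert_array_equal(out.environment_class.values,
                                  out.sensitivity_class.values)


def test_superpose_is_symmetric_under_swap(rng):
    a = make_grid(rng.uniform(0, 5, (10, 10)))
    b = make_grid(rng.uniform(0, 9, (10, 10)))
    ab = superpose_environment(a, b)
    ba = superpose_environment(b, a)
    np.testing.assert_array_equal(ab.environment_class.values,
                                  ba.environment_class.values)


def test_superpose_yields_five_nonempty_classes(rng):
    sens = make_grid(rng.uniform(1, 9, (20, 20)))
    imp = make_grid(rng.uniform(0, 1, (20, 20)))
    out = superpose_environment(sens, imp)
    present = set(np.unique(out.environment_class.values).astype(int))
    assert present == {1, 2, 3, 4, 5}


def test_superpose_deterministic(rng):
    sens = make_grid(rng.uniform(1, 9, (15, 15)))
    imp = make_grid(rng.uniform(0, 1, (15, 15)))
    a = superpose_environment(sens, imp)
    b = superpose_environment(sens.copy(), imp.copy())
    np.testing.assert_array_equal(a.environment_class.values,
                                  b.environment_class.values)


def test_slope_degrees_on_plane():
    # plane rising 1 m per 10 m of northing: slope = atan(0.1) ~ 5.71 deg
    rows = np.arange(6, dtype=float)[:, None] * np.ones((1, 6))
    dem = make_grid(rows, cellsize=10.0)
    slope = slope_degrees(dem)
    np.testing.assert_allclose(slope.values[2:4, 2:4], np.degrees(np.arctan(0.1)),
                               atol=1e-6)
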