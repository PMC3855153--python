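"""Correlations, partial correlations, asymptotic limits and the CI test."""

import numpy as np
import pytest
from scipy import stats

from noisenet import (
    analytic_dependencies,
    asymptotic_limits,
    build_motif,
    ci_test,
    sample_correlation,
    sample_dependencies,
    sample_partial_correlation,
    simulate,
)
from noisenet.dependence import PROFILE_FIELDS, partial_correlation_from_matrix
from noisenet.motif_models import MotifKind


def test_sample_correlation_examples(rng):
    x = rng.standard_normal(100)
    assert np.isclose(sample_correlation(x, x), 1.0)
    assert np.isclose(sample_correlation(x, -x), -1.0)
    r = sample_correlation(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 4.0]))
    assert np.isclose(r, 0.9608, atol=5e-5)  # 4 / sqrt(2 * 78/9), by hand


def test_sample_correlation_errors():
    with pytest.raises(ValueError):
        sample_correlation(np.ones(10), np.arange(10.0))
    with pytest.raises(ValueError):
        sample_correlation(np.arange(5.0), np.arange(4.0))


def test_partial_correlation_recursion_formula():
    # rxy=0, rxz=ryz=0.7  =>  -0.49 / 0.51 = -0.9608
    corr = np.array([[1.0, 0.0, 0.7], [0.0, 1.0, 0.7], [0.7, 0.7, 1.0]])
    r = partial_correlation_from_matrix(corr, 0, 1, [2])
    assert np.isclose(r, -0.49 / 0.51)


def test_sample_partial_matches_matrix_route(rng):
    data = rng.standard_normal((500, 3)) @ rng.standard_normal((3, 3))
    by_recursion = sample_partial_correlation(data[:, 0], data[:, 1], data[:, 2])
    by_precision = partial_correlation_from_matrix(np.corrcoef(data, rowvar=False), 0, 1, [2])
    assert np.isclose(by_recursion, by_precision)


def test_chain_conditioning_on_mediator_renders_independent():
    data = simulate(build_motif("three_chain", 1.0, (1, 1, 1)), 100_000, seed=3)
    r = sample_partial_correlation(data.column("x"), data.column("z"), data.column("y"))
    assert abs(r) < 0.02


def test_analytic_dependencies_structural_zeros():
    for scales in [(1, 1, 1), (1, 5, 0.2)]:
        assert analytic_dependencies(build_motif("common_effect", 1.3, scales)).rho_xy == 0.0
        assert np.isclose(
            analytic_dependencies(build_motif("three_chain", 1.3, scales)).rho_xz_y, 0.0
        )


def test_chain_correlation_factorizes():
    prof = analytic_dependencies(build_motif("three_chain", 1.0, (1, 1, 1)))
    assert np.isclose(prof.rho_xz, prof.rho_xy * prof.rho_yz)
    assert np.isclose(prof.rho_xz, 1 / np.sqrt(3))


@pytest.mark.parametrize("kind", list(MotifKind))
@pytest.mark.parametrize("coupling", [0.5, 1.0, 2.0])
@pytest.mark.parametrize("scales", [(1, 1, 1), (1, 10, 1), (1, 1, 10)])
def test_analytic_agrees_with_monte_carlo(kind, coupling, scales):
    """Brute-force n=1e6 sample dependencies as the oracle for the closed form."""
    model = build_motif(kind, coupling, scales)
    analytic = analytic_dependencies(model).as_array()
    sampled = sample_dependencies(simulate(model, 1_000_000, seed=77)).as_array()
    se = (1 - analytic**2) / np.sqrt(1_000_000) + 1e-12
    assert np.all(np.abs(sampled - analytic) < 5 * se + 1e-4)


# Parameter-free asymptotic table entries: (kind, limit node) -> six limits,
# None marking cells that remain functions of the parameters.
TABLE_ROWS = {
    ("common_effect", "y"): (0, 0, 1, None, None, 1),
    ("three_chain", "y"): (0, 0, 1, 0, 0, 1),
    ("ffl_type1", "y"): (0, 0, 1, None, None, 1),
    ("common_effect", "z"): (0, 0, 0, 0, 0, 0),
    ("three_chain", "z"): (None, 0, 0, None, 0, 0),
    ("ffl_type1", "z"): (None, 0, 0, None, 0, 0),
}


@pytest.mark.parametrize("kind,node", list(TABLE_ROWS))
def test_asymptotic_limits_match_table(kind, node):
    res = asymptotic_limits(kind, node, coupling=1.0, finite_scales=(1.0, 1.0))
    for name, expected in zip(PROFILE_FIELDS, TABLE_ROWS[(kind, node)]):
        got = getattr(res.profile, name)
        if expected is None:
            assert res.parameter_dependent[name]
            assert abs(got) > 1e-9
        else:
            assert not res.parameter_dependent[name]
            assert abs(got - expected) < 1e-12


@pytest.mark.parametrize("kind,node", list(TABLE_ROWS))
def test_limits_consistent_with_large_scale_evaluation(kind, node):
    """The algebraic limit must agree with the closed form evaluated at 1e6."""
    res = asymptotic_limits(kind, node, coupling=2.0, finite_scales=(1.0, 1.5))
    scales = (1.0, 1e6, 1.5) if node == "y" else (1.0, 1.5, 1e6)
    numeric = analytic_dependencies(build_motif(kind, 2.0, scales))
    assert np.allclose(res.profile.as_array(), numeric.as_array(), atol=1e-3)


def test_common_effect_limit_partials_mirror_sign():
    """Large noise at one cause: the two cause-partials have equal magnitude
    and opposite signs, a function of the coupling."""
    res = asymptotic_limits("common_effect", "y", coupling=2.0, finite_scales=(1.0, 1.0))
    p = res.profile
    assert np.isclose(abs(p.rho_xy_z), abs(p.rho_xz_y))
    assert np.sign(p.rho_xy_z) == -np.sign(p.rho_xz_y)
    assert abs(p.rho_xy_z) > 0.1


def test_ffl_indistinguishable_from_chain_in_parameter_free_cells():
    for node in ("y", "z"):
        ffl = asymptotic_limits("ffl_type1", node, 2.0, (1.0, 1.0))
        chain = asymptotic_limits("three_chain", node, 2.0, (1.0, 1.0))
        for name in PROFILE_FIELDS:
            if ffl.parameter_dependent[name] or chain.parameter_dependent[name]:
                continue
            assert np.isclose(
                getattr(ffl.profile, name), getattr(chain.profile, name), atol=1e-12
            )


def test_asymptotic_limits_rejects_bad_node():
    with pytest.raises(ValueError):
        asymptotic_limits("three_chain", "x", 1.0, (1.0, 1.0))


def test_ci_test_statistic_formula(faithful_datasets):
    data = faithful_datasets["three_chain"]
    res = ci_test(data, "x", "y", (), alpha=0.01)
    expected_t = res.r * np.sqrt((data.n - 2) / (1 - res.r**2))
    assert np.isclose(res.statistic, expected_t)
    assert res.df == data.n - 2
    cond = ci_test(data, "x", "z", ("y",), alpha=0.01)
    assert cond.df == data.n - 3
    assert cond.independent  # mediator separates x and z


def test_ci_test_zero_correlation_gives_p_one():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    # orthogonalize y against x exactly
    y = y - np.polyval(np.polyfit(x, y, 1), x)
    from noisenet import ExpressionMatrix

    res = ci_test(ExpressionMatrix(np.column_stack([x, y]), ["a", "b"]), "a", "b")
    assert abs(res.r) < 1e-12
    assert res.p_value > 0.999
    assert res.independent


def test_ci_test_insufficient_samples():
    from noisenet import ExpressionMatrix

    tiny = ExpressionMatrix(np.random.default_rng(0).standard_normal((4, 3)), ["a", "b", "c"])
    with pytest.raises(ValueError, match="insufficient"):
        ci_test(tiny, "a", "b", ("c",))


def test_ci_test_null_p_values_uniform(rng):
    """Under independence, the test's two-sided p-values are Uniform(0,1)."""
    from noisenet import ExpressionMatrix

    reps, n = 2000, 300
    p_values = np.empty(reps)
    for i in range(reps):
        data = ExpressionMatrix(rng.standard_normal((n, 2)), ["a", "b"])
        p_values[i] = ci_test(data, "a", "b").p_value
    d = stats.kstest(p_values, "uniform").statistic
    assert d < 0.04
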