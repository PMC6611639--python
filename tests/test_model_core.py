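"""Unit and property tests for the core model: params, simulate, errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qscrosstalk as q
from qscrosstalk.errors import (
    DegenerateBaselineError,
    DimensionError,
    IntegrationError,
)
from qscrosstalk.simulate import effective_concentration, hill_activation


# ---------------------------------------------------------------------------
# effective concentration

def test_effective_concentration_identity():
    assert effective_concentration(np.array([1.0]), np.array([2.0])) == 2.0


def test_effective_concentration_clamps_net_inhibition_to_zero():
    assert effective_concentration(np.array([1.0, -1.0]), np.array([1.0, 2.0])) == 0.0


def test_effective_concentration_weighted_sum():
    out = effective_concentration(np.array([1.0, 0.445]), np.array([1.0, 1.0]))
    assert out == pytest.approx(1.445)


def test_effective_concentration_dimension_mismatch():
    with pytest.raises(DimensionError):
        effective_concentration(np.array([1.0, 0.5]), np.array([1.0]))


def test_effective_concentration_rejects_negative_concentration():
    with pytest.raises(ValueError):
        effective_concentration(np.array([1.0]), np.array([-0.1]))


@given(
    w=st.lists(st.floats(-3, 3), min_size=1, max_size=6),
    c=st.lists(st.floats(0, 30), min_size=1, max_size=6),
)
@settings(max_examples=50, derandomize=True)
def test_effective_concentration_always_nonnegative(w, c):
    k = min(len(w), len(c))
    out = effective_concentration(np.array(w[:k]), np.array(c[:k]))
    assert out >= 0.0


# ---------------------------------------------------------------------------
# Hill activation

def test_hill_zero_signal_gives_zero():
    assert hill_activation(0.0, theta=1.5, m=2.0) == 0.0


def test_hill_half_maximal_at_theta():
    assert hill_activation(1.5, theta=1.5, m=2.0) == pytest.approx(0.5)


def test_hill_saturates_to_one():
    assert hill_activation(1.5e4, theta=1.5, m=2.0) > 1.0 - 1e-6


def test_hill_monotone_on_array():
    c = np.linspace(0.0, 30.0, 200)
    h = hill_activation(c, theta=1.5, m=2.0)
    assert np.all(np.diff(h) > 0)
    assert np.all((h >= 0) & (h < 1))


def test_hill_rejects_invalid_parameters():
    with pytest.raises(ValueError):
        hill_activation(1.0, theta=0.0, m=2.0)
    with pytest.raises(ValueError):
        hill_activation(-1.0, theta=1.0, m=2.0)


# ---------------------------------------------------------------------------
# parameter containers

def test_strain_params_validation():
    with pytest.raises(ValueError):
        q.StrainParams(strain_id="X", f=-1.0, theta=1.0)
    with pytest.raises(ValueError):
        q.StrainParams(strain_id="X", f=1.0, theta=0.0)


def test_weight_matrix_requires_unit_diagonal():
    with pytest.raises(ValueError):
        q.WeightMatrix(("A", "B"), np.array([[0.9, 0.0], [0.0, 1.0]]))


def test_weight_matrix_row_lookup(fixture_W):
    assert fixture_W.row("C")[0] == pytest.approx(0.445)
    with pytest.raises(KeyError):
        fixture_W.index("Z")


def test_environment_rejects_overfull_inoculum():
    with pytest.raises(ValueError):
        q.EnvironmentParams(n0=(6e8, 6e8))


def test_signal_mixture_parse_and_concentration():
    mix = q.SignalMixture.parse("A=10, B=4")
    assert mix.concentration("A") == pytest.approx(1.5)
    assert mix.concentration("B") == pytest.approx(0.6)
    assert mix.concentration("C") == 0.0


def test_strain_table_roundtrip(tmp_path, strains):
    path = tmp_path / "strains.csv"
    q.save_strain_table(strains, path)
    loaded = q.load_strain_table(path)
    assert loaded == strains


def test_weight_matrix_roundtrip(tmp_path, fixture_W):
    path = tmp_path / "w.csv"
    q.save_weight_matrix(fixture_W, path)
    loaded = q.load_weight_matrix(path)
    assert loaded.strain_order == fixture_W.strain_order
    assert np.allclose(loaded.w, fixture_W.w)


# ---------------------------------------------------------------------------
# logistic growth vs closed form


def _closed_form_logistic(t_min, n0, mu_per_h, s):
    g = np.exp(mu_per_h / 60.0 * t_min)
    return s * n0 * g / (s + n0 * (g - 1.0))


def test_logistic_matches_closed_form_at_final_time_dt1(strain_map):
    p = strain_map["A"]
    env = q.EnvironmentParams.coculture_default(1)
    res = q.simulate([p], q.WeightMatrix.identity(["A"]), env)
    exact = _closed_form_logistic(res.times[-1], env.n0[0], p.mu, env.s)
    assert abs(res.n[0, -1] / exact - 1.0) < 1e-3


def test_logistic_matches_closed_form_pointwise_at_refined_dt(strain_map):
    p = strain_map["A"]
    env = q.EnvironmentParams.coculture_default(1, dt=0.01)
    res = q.simulate([p], q.WeightMatrix.identity(["A"]), env)
    exact = _closed_form_logistic(res.times, env.n0[0], p.mu, env.s)
    assert np.max(np.abs(res.n[0] / exact - 1.0)) < 1e-3


# ---------------------------------------------------------------------------
# reporter vs analytic solution (constant population, constant signal)

def test_reporter_matches_analytic_relaxation(strain_map):
    from dataclasses import replace

    p = replace(strain_map["C"], mu=0.0)  # constant population
    env = q.EnvironmentParams.tester_default()
    c0 = 2.0 * p.theta
    res = q.simulate(
        [p], q.WeightMatrix.identity(["C"]), env,
        init_c=[c0], produce_signal=[False], tester=0,
    )
    boost = p.f * hill_activation(c0, p.theta, p.m) + 1.0
    L_inf = p.rho_L * env.n0[0] * boost / p.gamma_L
    exact = L_inf * (1.0 - np.exp(-p.gamma_L * res.times))
    mask = res.times >= 5.0 / p.gamma_L  # past the transient
    assert np.max(np.abs(res.L[mask] / exact[mask] - 1.0)) < 0.01


# ---------------------------------------------------------------------------
# simulate: invariants, convergence, failure modes

@given(
    mu=st.floats(0.1, 3.0),
    n0=st.floats(1e4, 5e8),
    c0=st.floats(0.0, 30.0),
    w=st.floats(-2.0, 2.0),
)
@settings(max_examples=15, deadline=None, derandomize=True)
def test_states_stay_nonnegative_and_bounded(mu, n0, c0, w, strain_map):
    from dataclasses import replace

    a = replace(strain_map["A"], mu=mu)
    b = replace(strain_map["B"], mu=mu)
    W = q.WeightMatrix(("A", "B"), np.array([[1.0, w], [w, 1.0]]))
    env = q.EnvironmentParams.coculture_default(2, duration=4.0, n0=(n0 / 2, n0 / 2))
    res = q.simulate([a, b], W, env, init_c=[c0, c0], tester=0)
    assert np.all(res.n >= 0) and np.all(res.c >= 0) and np.all(res.L >= 0)
    assert np.all(res.n.sum(axis=0) <= env.s * 1.001)


def test_euler_dt_halving_changes_final_state_little(strains, W_AB):
    a, b = strains[0], strains[1]
    res1 = q.simulate_coculture([a, b], W_AB, env=q.EnvironmentParams.coculture_default(2))
    res2 = q.simulate_coculture(
        [a, b], W_AB, env=q.EnvironmentParams.coculture_default(2, dt=0.5)
    )
    assert np.max(np.abs(res1.final_c() / res2.final_c() - 1.0)) < 0.005
    assert np.max(np.abs(res1.n[:, -1] / res2.n[:, -1] - 1.0)) < 0.005


def test_integration_error_names_variable_and_time(strain_map):
    from dataclasses import replace

    p = replace(strain_map["A"], rho_c=1e300)
    env = q.EnvironmentParams.coculture_default(1)
    with pytest.raises(IntegrationError, match="'c'"):
        q.simulate([p], q.WeightMatrix.identity(["A"]), env)


def test_simulate_dimension_checks(strains, W_AB):
    env = q.EnvironmentParams.coculture_default(2)
    with pytest.raises(DimensionError):
        q.simulate(strains[:3], W_AB, env)
    with pytest.raises(DimensionError):
        q.simulate(strains[:2], W_AB, env, init_c=[1.0])


def test_bolus_after_duration_rejected(strain_map):
    env = q.EnvironmentParams.coculture_default(1)
    with pytest.raises(ValueError):
        q.simulate(
            [strain_map["A"]], q.WeightMatrix.identity(["A"]), env,
            boluses=[(601.0 * 60.0, 0, 1.0)],
        )


# ---------------------------------------------------------------------------
# fold change

def test_fold_change_is_one_without_signal(strain_map, tester_env):
    p = strain_map["A"]
    W = q.WeightMatrix.identity(["A"])
    base = q.simulate([p], W, tester_env, init_c=[0.0], produce_signal=[False], tester=0)
    assert q.fold_change(base, base) == pytest.approx(1.0)


def test_fold_change_saturating_approaches_f_plus_one(strain_map, tester_env):
    p = strain_map["C"]
    fold = q.fold_change_at(p, tester_env, 300.0 * p.theta)
    assert fold == pytest.approx(p.f + 1.0, rel=0.02)


def test_fold_change_at_theta_approaches_half_activation(strain_map, tester_env):
    p = strain_map["C"]
    fold = q.fold_change_at(p, tester_env, p.theta)
    assert fold == pytest.approx(p.f / 2.0 + 1.0, rel=0.02)


def test_fold_change_degenerate_baseline(strain_map, tester_env):
    from dataclasses import replace

    p = replace(strain_map["A"], rho_L=0.0)
    with pytest.raises(DegenerateBaselineError):
        q.fold_change_at(p, tester_env, 1.0)


def test_clamped_mixture_gives_fold_one(strain_map, tester_env):
    # net-inhibitory weighted sum -> zero effective signal -> fold 1
    p = strain_map["A"]
    c_eff = effective_concentration(np.array([1.0, -2.0]), np.array([1.0, 3.0]))
    assert c_eff == 0.0
    assert q.fold_change_at(p, tester_env, c_eff) == pytest.approx(1.0)


def test_fold_change_monotone_in_effective_signal(strain_map, tester_env):
    p = strain_map["B"]
    folds = q.fold_change_at(p, tester_env, np.linspace(0.0, 10.0, 50))
    assert np.all(np.diff(folds) > 0)


def test_fold_change_at_scalar_and_array_agree(strain_map, tester_env):
    p = strain_map["D"]
    arr = q.fold_change_at(p, tester_env, np.array([0.0, 1.0, 2.0]))
    assert q.fold_change_at(p, tester_env, 1.0) == pytest.approx(arr[1])


def test_two_run_fold_change_agrees_with_constant_signal_readout(
    strain_map, tester_env
):
    # the full simulator (constant exogenous bolus) and the vectorized
    # constant-signal readout must agree exactly
    p = strain_map["E"]
    W = q.WeightMatrix.identity(["E"])
    c0 = 2.5
    sig = q.simulate([p], W, tester_env, init_c=[c0], produce_signal=[False], tester=0)
    base = q.simulate([p], W, tester_env, init_c=[0.0], produce_signal=[False], tester=0)
    assert q.fold_change(sig, base) == pytest.approx(
        q.fold_change_at(p, tester_env, c0), rel=1e-12
    )


def test_tidy_export_roundtrip(tmp_path, strain_map, tester_env):
    p = strain_map["A"]
    res = q.simulate(
        [p], q.WeightMatrix.identity(["A"]), tester_env,
        init_c=[1.0], produce_signal=[False], tester=0,
    )
    df = res.to_tidy()
    assert set(df["variable"]) == {"n", "c", "L"}
    path = tmp_path / "run.csv"
    res.to_csv(path)
    assert path.exists()
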