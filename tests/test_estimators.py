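import math

import numpy as np
import pytest

from abfekit import (
    HarmonicSpec,
    LambdaSchedule,
    MBAR,
    aggregate_replicas,
    assemble_cycle,
    bar_solve,
    gen_ar1_series,
    gen_harmonic_ensemble,
    leg_free_energy,
    mbar_solve,
    statistical_inefficiency,
    subsample,
    ti_integrate,
)
from abfekit._constants import kt_kcal
from abfekit.estimators import CycleResult, StageFreeEnergy, decorrelate_leg

from conftest import make_window

# ---------------------------------------------------------------------------
# statistical inefficiency
# ---------------------------------------------------------------------------


def test_inefficiency_white_noise():
    rng = np.random.default_rng(11)
    g = statistical_inefficiency(rng.normal(size=100_000))
    assert 0.9 <= g <= 1.2


def test_inefficiency_ar1_closed_form():
    # g = (1+rho)/(1-rho) = 19 for rho = 0.9 (heavy n = 1e6 case in acceptance)
    series = gen_ar1_series(0.9, 200_000, seed=3)
    g = statistical_inefficiency(series)
    assert abs(g - 19.0) / 19.0 < 0.15


def test_inefficiency_constant_series():
    assert statistical_inefficiency(np.full(100, 2.5)) == 1.0


def test_inefficiency_short_series_errors():
    with pytest.raises(ValueError, match="too short"):
        statistical_inefficiency([1.0, 2.0, 3.0])


def test_inefficiency_clamped_at_one():
    # strictly alternating series is anticorrelated; g must clamp to >= 1
    x = np.tile([1.0, -1.0], 500)
    assert statistical_inefficiency(x) == 1.0


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------


def test_subsample_stride():
    w = make_window(n_frames=2000)
    out = subsample(w, g=10.0)
    assert out.n_frames == 200
    np.testing.assert_array_equal(out.times, w.times[::10])


def test_subsample_identity_for_g_one():
    w = make_window(n_frames=100)
    assert subsample(w, g=1.0) is w


def test_subsample_cap_keeps_min_frames():
    w = make_window(n_frames=2000)
    out = subsample(w, g=100.0)  # stride capped at 2000 // 50 = 40
    assert out.n_frames == 50
    np.testing.assert_array_equal(out.times, w.times[::40])


def test_subsample_rejects_g_below_one():
    with pytest.raises(ValueError, match=">= 1"):
        subsample(make_window(), g=0.5)


def test_decorrelate_leg_without_dhdl_is_identity():
    schedule = LambdaSchedule.single_stage("coul", (0.0, 1.0))
    from abfekit import LegEnsemble

    leg = LegEnsemble(
        schedule=schedule,
        windows=[make_window(n_stage_windows=2, window_index=i) for i in range(2)],
    )
    out = decorrelate_leg(leg)
    assert [w.n_frames for w in out.windows] == [w.n_frames for w in leg.windows]


# ---------------------------------------------------------------------------
# MBAR / BAR
# ---------------------------------------------------------------------------


def test_mbar_identical_potentials_exact_zero():
    rng = np.random.default_rng(0)
    u = np.tile(rng.normal(size=300), (4, 1))
    res = mbar_solve(u, [75, 75, 75, 75])
    np.testing.assert_allclose(res.f_k, 0.0, atol=1e-12)


def _harmonic_u_kn(K, n_per, seed):
    rng = np.random.default_rng(seed)
    K = np.asarray(K, dtype=float)
    xs = np.concatenate(
        [rng.normal(0.0, 1.0 / math.sqrt(k), size=n_per) for k in K]
    )
    u_kn = 0.5 * K[:, None] * xs[None, :] ** 2
    return u_kn, np.full(len(K), n_per)


def test_mbar_two_window_harmonic():
    u_kn, n_k = _harmonic_u_kn((1.0, 2.0), 10_000, seed=5)
    res = mbar_solve(u_kn, n_k)
    exact = 0.5 * math.log(2.0)
    assert abs(res.delta_f() - exact) <= 3.0 * res.d_delta_f()


def test_mbar_chain_additivity():
    u_kn, n_k = _harmonic_u_kn((1.0, 2.0, 4.0), 500, seed=9)
    res = mbar_solve(u_kn, n_k)
    assert res.delta_f(0, 2) == pytest.approx(
        res.delta_f(0, 1) + res.delta_f(1, 2), abs=1e-14
    )


def test_mbar_matches_frozen_reference_implementation():
    """Cross-check against pymbar 4.0.3 on a frozen fixture.

    The fixture is regenerated deterministically here; the expected values
    were computed once with pymbar.MBAR (solving to 1e-12) and frozen.
    """
    rng = np.random.default_rng(20240915)
    K = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
    n_k = np.array([80, 100, 120, 90, 110])
    xs = np.concatenate(
        [rng.normal(0.0, 1.0 / np.sqrt(k), size=n) for k, n in zip(K, n_k)]
    )
    u_kn = 0.5 * K[:, None] * xs[None, :] ** 2
    res = mbar_solve(u_kn, n_k, tol=1e-12)
    expected_f = np.array(
        [
            0.0,
            0.354057372502921,
            0.7081510832064888,
            1.0505783384276963,
            1.3905265400246734,
        ]
    )
    np.testing.assert_allclose(res.f_k, expected_f, atol=1e-6)
    assert res.d_delta_f() == pytest.approx(0.07639245347361615, abs=1e-6)


def test_mbar_equals_bar_for_two_states():
    u_kn, n_k = _harmonic_u_kn((1.0, 3.0), 2_000, seed=17)
    res = mbar_solve(u_kn, n_k, tol=1e-12)
    w_f = u_kn[1, : n_k[0]] - u_kn[0, : n_k[0]]
    w_r = u_kn[0, n_k[0]:] - u_kn[1, n_k[0]:]
    df_bar = bar_solve(w_f, w_r, tol=1e-14)
    assert abs(res.delta_f() - df_bar) < 1e-6


def test_mbar_rejects_empty_state():
    u = np.zeros((2, 10))
    with pytest.raises(ValueError, match="at least one sample"):
        MBAR(u, [10, 0])


def test_mbar_rejects_mismatched_counts():
    u = np.zeros((2, 10))
    with pytest.raises(ValueError, match="does not match"):
        MBAR(u, [4, 4])


def test_mbar_non_convergence_carries_residual():
    from abfekit.estimators import ConvergenceError

    u_kn, n_k = _harmonic_u_kn((1.0, 2.0, 4.0), 200, seed=1)
    with pytest.raises(ConvergenceError) as err:
        mbar_solve(u_kn, n_k, tol=1e-30, max_iter=2)
    assert np.isfinite(err.value.residual)


def test_mbar_overlap_matrix_rows_sum_to_one():
    u_kn, n_k = _harmonic_u_kn((1.0, 2.0, 4.0), 400, seed=23)
    res = mbar_solve(u_kn, n_k)
    np.testing.assert_allclose(res.overlap_matrix.sum(axis=1), 1.0, atol=1e-10)


def test_mbar_invariant_to_per_sample_offsets():
    # adding a per-sample constant to every state's u leaves f_k unchanged:
    # justifies storing Delta-H relative to the sampling window
    u_kn, n_k = _harmonic_u_kn((1.0, 2.0), 500, seed=2)
    shift = np.random.default_rng(3).normal(size=u_kn.shape[1])
    res_a = mbar_solve(u_kn, n_k, tol=1e-12)
    res_b = mbar_solve(u_kn + shift[None, :], n_k, tol=1e-12)
    np.testing.assert_allclose(res_a.f_k, res_b.f_k, atol=1e-8)


def test_bar_simple_shift():
    # u_1 = u_0 + c: every forward work value is c, reverse is -c -> df = c
    w_f = np.full(100, 1.7)
    w_r = np.full(80, -1.7)
    assert bar_solve(w_f, w_r) == pytest.approx(1.7, abs=1e-9)


def test_bar_requires_both_sides():
    with pytest.raises(ValueError, match="both states"):
        bar_solve([], [1.0])


# ---------------------------------------------------------------------------
# leg-level estimation
# ---------------------------------------------------------------------------


def test_leg_free_energy_harmonic_within_3se():
    lams = tuple(np.linspace(0.0, 1.0, 11))
    spec = HarmonicSpec.linear(1.0, 4.0, lams, n_samples=2000, seed=42)
    leg, analytic = gen_harmonic_ensemble(
        spec, LambdaSchedule.single_stage("coul", lams)
    )
    (stage,) = leg_free_energy(leg)
    kt = kt_kcal(leg.temperature)
    assert stage.method == "mbar"
    assert abs(stage.delta_g / kt - analytic["coul"]) <= 3.0 * stage.uncertainty / kt


def test_leg_free_energy_identical_windows_zero():
    lams = (0.0, 0.5, 1.0)
    spec = HarmonicSpec.linear(2.0, 2.0, lams, n_samples=500, seed=8)
    leg, analytic = gen_harmonic_ensemble(
        spec, LambdaSchedule.single_stage("vdw", lams)
    )
    (stage,) = leg_free_energy(leg)
    assert analytic["vdw"] == 0.0
    assert stage.delta_g == pytest.approx(0.0, abs=1e-10)


def test_leg_free_energy_zero_sample_window_errors():
    lams = (0.0, 1.0)
    spec = HarmonicSpec.linear(1.0, 2.0, lams, n_samples=100, seed=0)
    leg, _ = gen_harmonic_ensemble(spec, LambdaSchedule.single_stage("coul", lams))
    leg.windows[1] = leg.windows[1].sliced(slice(0, 0))
    with pytest.raises(ValueError):
        leg_free_energy(leg)


def test_ti_constant_dhdl():
    lams = (0.0, 0.5, 1.0)
    schedule = LambdaSchedule.single_stage("coul", lams)
    from abfekit import LegEnsemble

    c = -3.25
    windows = [
        make_window(n_frames=50, n_stage_windows=3, window_index=i,
                    dhdl=np.full((50, 1), c) + np.linspace(0, 1e-9, 50)[:, None])
        for i in range(3)
    ]
    leg = LegEnsemble(schedule=schedule, windows=windows)
    (stage,) = ti_integrate(leg)
    assert stage.method == "ti"
    assert stage.delta_g == pytest.approx(c, abs=1e-8)


def test_ti_dense_harmonic_within_2pct():
    lams = tuple(np.linspace(0.0, 1.0, 21))
    spec = HarmonicSpec.linear(1.0, 4.0, lams, n_samples=5000, seed=31)
    leg, analytic = gen_harmonic_ensemble(
        spec, LambdaSchedule.single_stage("vdw", lams)
    )
    (stage,) = ti_integrate(leg)
    kt = kt_kcal(leg.temperature)
    exact = analytic["vdw"]
    assert abs(stage.delta_g / kt - exact) / abs(exact) < 0.02


def test_ti_single_window_stage_errors():
    schedule = LambdaSchedule(stages=(("coul", (0.0,)),), leg_kind="solvent")
    from abfekit import LegEnsemble

    leg = LegEnsemble(
        schedule=schedule,
        windows=[make_window(n_stage_windows=1, dhdl=np.ones((10, 1)))],
    )
    with pytest.raises(ValueError, match="fewer than 2"):
        ti_integrate(leg)


def test_ti_missing_dhdl_errors():
    schedule = LambdaSchedule.single_stage("coul", (0.0, 1.0))
    from abfekit import LegEnsemble

    leg = LegEnsemble(
        schedule=schedule,
        windows=[make_window(n_stage_windows=2, window_index=i) for i in range(2)],
    )
    with pytest.raises(ValueError, match="no dH/dlambda"):
        ti_integrate(leg)


# ---------------------------------------------------------------------------
# cycle assembly
# ---------------------------------------------------------------------------


def _stage(name, dg, unc=0.0):
    return StageFreeEnergy(
        stage_name=name, delta_g=dg, uncertainty=unc, n_effective=np.array([10, 10])
    )


def test_assemble_cycle_arithmetic():
    res = assemble_cycle(
        solvent_stages=[_stage("coul", 5.0), _stage("vdw", 3.0)],
        complex_stages=[_stage("restraint", 0.5), _stage("coul", 6.0), _stage("vdw", 15.0)],
        restraint_on_analytic=7.0,
    )
    assert res.delta_g_bind == pytest.approx(-6.5, abs=1e-10)


def test_assemble_cycle_all_zero_stages():
    res = assemble_cycle(
        solvent_stages=[_stage("coul", 0.0), _stage("vdw", 0.0)],
        complex_stages=[_stage("restraint", 0.0), _stage("coul", 0.0), _stage("vdw", 0.0)],
        restraint_on_analytic=7.0,
    )
    assert res.delta_g_bind == pytest.approx(7.0, abs=1e-10)


def test_assemble_cycle_cancellation():
    res = assemble_cycle(
        solvent_stages=[_stage("coul", 4.2), _stage("vdw", -1.3)],
        complex_stages=[_stage("restraint", 0.0), _stage("coul", 4.2), _stage("vdw", -1.3)],
        restraint_on_analytic=-6.83,
    )
    assert res.delta_g_bind == pytest.approx(-6.83, abs=1e-10)


def test_assemble_cycle_antisymmetry():
    rng = np.random.default_rng(4)
    sc, sv, cr, cc, cv, an, corr = rng.normal(size=7)
    fwd = assemble_cycle(
        solvent_stages=[_stage("coul", sc), _stage("vdw", sv)],
        complex_stages=[_stage("restraint", cr), _stage("coul", cc), _stage("vdw", cv)],
        restraint_on_analytic=an,
        charge_correction=corr,
    )
    # swap solvent and complex roles (restraint moves sign via the analytic term)
    rev = assemble_cycle(
        solvent_stages=[_stage("coul", cc), _stage("vdw", cv)],
        complex_stages=[_stage("restraint", -cr), _stage("coul", sc), _stage("vdw", sv)],
        restraint_on_analytic=-an,
        charge_correction=-corr,
    )
    assert rev.delta_g_bind == pytest.approx(-fwd.delta_g_bind, abs=1e-10)


def test_assemble_cycle_uncertainty_quadrature():
    res = assemble_cycle(
        solvent_stages=[_stage("coul", 0.0, 0.3), _stage("vdw", 0.0, 0.4)],
        complex_stages=[
            _stage("restraint", 0.0, 0.1),
            _stage("coul", 0.0, 0.2),
            _stage("vdw", 0.0, 0.2),
        ],
        restraint_on_analytic=0.0,
    )
    assert res.uncertainty == pytest.approx(
        math.sqrt(0.3**2 + 0.4**2 + 0.1**2 + 0.2**2 + 0.2**2), abs=1e-12
    )


def test_assemble_cycle_missing_stage_errors():
    with pytest.raises(ValueError, match="complex:restraint"):
        assemble_cycle(
            solvent_stages=[_stage("coul", 0.0), _stage("vdw", 0.0)],
            complex_stages=[_stage("coul", 0.0), _stage("vdw", 0.0)],
            restraint_on_analytic=0.0,
        )


def test_assemble_cycle_components_consistent():
    res = assemble_cycle(
        solvent_stages=[_stage("coul", 1.0), _stage("vdw", 2.0)],
        complex_stages=[_stage("restraint", 0.25), _stage("coul", 3.0), _stage("vdw", 4.0)],
        restraint_on_analytic=-6.0,
        charge_correction=0.5,
    )
    c = res.components
    recombined = (
        c["solvent_coul"] + c["solvent_vdw"] + c["restraint_on_analytic"]
        - (c["complex_restraint"] + c["complex_coul"] + c["complex_vdw"])
        + c["charge_correction"]
    )
    assert res.delta_g_bind == pytest.approx(recombined, abs=1e-10)


# ---------------------------------------------------------------------------
# replica aggregation
# ---------------------------------------------------------------------------


def _cycle(ligand, dg, replica="r1"):
    return CycleResult(
        ligand_id=ligand, replica_id=replica, delta_g_bind=dg, uncertainty=0.1, components={}
    )


def test_aggregate_three_replicas():
    agg = aggregate_replicas([_cycle("L", -10.0), _cycle("L", -11.0), _cycle("L", -12.0)])
    assert agg.mean == pytest.approx(-11.0)
    assert agg.replica_std == pytest.approx(1.0)
    assert agg.n_replicas == 3


def test_aggregate_identical_values_zero_std():
    agg = aggregate_replicas([_cycle("L", -9.5)] * 5)
    assert agg.replica_std == 0.0


def test_aggregate_five_replicas_arithmetic():
    values = (-12.5, -11.9, -12.2, -13.0, -11.4)
    agg = aggregate_replicas([_cycle("L", v) for v in values])
    assert agg.mean == pytest.approx(-12.2, abs=1e-12)
    # ddof=1: sum of squared deviations 1.46 over 4 -> 0.60415...
    assert agg.replica_std == pytest.approx(math.sqrt(1.46 / 4.0), abs=1e-12)


def test_aggregate_single_replica_std_undefined():
    agg = aggregate_replicas([_cycle("L", -8.0)])
    assert agg.replica_std is None
    assert agg.n_replicas == 1


def test_aggregate_mixed_ligands_errors():
    with pytest.raises(ValueError, match="mixed ligand ids"):
        aggregate_replicas([_cycle("A", -8.0), _cycle("B", -8.0)])
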