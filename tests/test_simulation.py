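import numpy as np
import pytest

from osteosim import core
from osteosim.core import BoneState
from osteosim.parameters import reference_parameters
from osteosim.pharmacology import DoseEvent, Regimen, make_block_regimen
from osteosim.physiology import EstrogenCurve, curve_from_parameters
from osteosim.simulate import (
    N_BONE,
    bmd,
    bmd_relative,
    btm_observables,
    coupled_rhs,
    simulate,
)


from oracles import bateman_central, rk4_reference


# ---------------------------------------------------------------------------
# fixed point and determinism


def test_steady_state_invariance_over_fifty_years(ref_params):
    """At constant premenopausal estrogen and no drugs the trajectory is flat."""
    curve = EstrogenCurve.constant(1.0)
    traj = simulate(ref_params, curve, age_span=(25.0, 75.0))
    drift = np.abs(traj.states - 1.0)
    assert drift.max() < 1e-3  # < 0.1 % over 50 years


def test_empty_regimen_equals_zero_length_block_list(ref_params):
    grid = np.linspace(25, 40, 301)
    a = simulate(ref_params, regimen=None, age_span=(25, 40), output_grid=grid)
    b = simulate(
        ref_params,
        regimen=make_block_regimen([], start_age=30),
        age_span=(25, 40),
        output_grid=grid,
    )
    assert np.array_equal(a.states, b.states)
    for key in a.observables:
        assert np.array_equal(a.observables[key], b.observables[key])


def test_identical_inputs_identical_trajectories(ref_params):
    reg = make_block_regimen([("denosumab", 60, 0.5, 1.0)], start_age=60)
    a = simulate(ref_params, regimen=reg, age_span=(55, 62))
    b = simulate(ref_params, regimen=reg, age_span=(55, 62))
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.drug_states["denosumab"], b.drug_states["denosumab"])


def test_grid_invariance(ref_params):
    reg = make_block_regimen([("denosumab", 60, 0.5, 1.0)], start_age=60)
    coarse = np.linspace(58, 63, 251)
    fine = np.linspace(58, 63, 501)  # halved spacing, shares coarse points
    a = simulate(ref_params, regimen=reg, age_span=(58, 63), output_grid=coarse)
    b = simulate(ref_params, regimen=reg, age_span=(58, 63), output_grid=fine)
    for key in a.observables:
        assert np.allclose(a.observables[key], b.observables[key][::2], atol=1e-9)


# ---------------------------------------------------------------------------
# integrator correctness against the brute-force oracle


def test_adaptive_integrator_matches_fixed_step_oracle(ref_params):
    """LSODA with dose events agrees with segmented RK4 at step 1e-4 yr."""
    t0, t1 = 60.0, 63.0
    curve = curve_from_parameters(ref_params)
    reg = make_block_regimen([("denosumab", 60, 0.5, 2.0)], start_age=60.5)
    traj = simulate(ref_params, curve, reg, age_span=(t0, t1))
    y_end = np.concatenate(
        [traj.states[-1], traj.drug_states["denosumab"][-1]]
    )

    p = ref_params.compile()
    fun = coupled_rhs(p, curve, ["denosumab"])
    y0 = np.concatenate([core.steady_state(p, curve(t0)).as_array(), np.zeros(3)])
    jump = np.zeros(len(y0))
    jump[N_BONE] = 60.0 * p.pk_denosumab_F
    dose_jumps = {t: jump for t in (60.5, 61.0, 61.5, 62.0)}
    y_ref = rk4_reference(fun, t0, t1, y0, 1e-4, dose_jumps)

    rel = np.abs(y_end - y_ref) / np.maximum(np.abs(y_ref), 1e-8)
    assert rel.max() < 1e-6


# ---------------------------------------------------------------------------
# pharmacokinetics against the closed form


def test_single_dose_follows_bateman_curve(ref_params):
    p = ref_params.compile()
    reg = Regimen(
        events=[DoseEvent("denosumab", 60.0, 60.0)]
    )
    grid = np.linspace(60.0, 61.0, 201)
    traj = simulate(
        ref_params,
        regimen=reg,
        age_span=(60.0, 61.0),
        output_grid=grid,
        rtol=1e-11,
        atol=1e-13,
    )
    central = traj.drug_states["denosumab"][:, 1]
    exact = bateman_central(grid - 60.0, 60.0, p.pk_denosumab_ka, p.pk_denosumab_ke)
    assert np.max(np.abs(central - exact)) / exact.max() < 1e-8


def test_pk_superposition_of_two_doses(ref_params):
    """Linearity: two boluses equal the sum of time-shifted single doses."""
    p = ref_params.compile()
    events = [
        DoseEvent("denosumab", 60.0, 60.0),
        DoseEvent("denosumab", 60.4, 60.0),
    ]
    grid = np.linspace(60.0, 61.2, 241)
    traj = simulate(
        ref_params,
        regimen=Regimen(events=events),
        age_span=(60.0, 61.2),
        output_grid=grid,
        rtol=1e-11,
        atol=1e-13,
    )
    central = traj.drug_states["denosumab"][:, 1]
    exact = bateman_central(
        grid - 60.0, 60.0, p.pk_denosumab_ka, p.pk_denosumab_ke
    ) + np.where(
        grid >= 60.4,
        bateman_central(
            np.clip(grid - 60.4, 0, None), 60.0, p.pk_denosumab_ka, p.pk_denosumab_ke
        ),
        0.0,
    )
    assert np.max(np.abs(central - exact)) / exact.max() < 1e-8


def test_ctx_suppression_monotone_in_dose(ref_params):
    """Stronger single denosumab doses suppress CTX at least as much."""
    suppressions = []
    for dose in (5.0, 20.0, 60.0):
        reg = Regimen(events=[DoseEvent("denosumab", 60.05, dose)])
        traj = simulate(ref_params, regimen=reg, age_span=(60.0, 60.4))
        i = np.argmin(np.abs(traj.times - 60.15))
        suppressions.append(traj.observables["ctx_change"][i])
    assert suppressions[0] >= suppressions[1] >= suppressions[2]
    assert suppressions[2] < 0


# ---------------------------------------------------------------------------
# observables


def test_bmd_is_product_of_density_and_mineral_content(ref_params):
    assert bmd(BoneState(rho=0.9, mc=1.0)) == pytest.approx(0.9)
    assert bmd(BoneState(rho=1.8, mc=2.0)) == pytest.approx(4 * bmd(BoneState(rho=0.9, mc=1.0)))
    traj = simulate(ref_params, age_span=(25, 60))
    assert np.allclose(
        traj.bmd_series, traj.column("rho") * traj.column("mc"), atol=1e-12
    )


def test_bmd_relative_normalized_at_reference_age(ref_params):
    traj = simulate(ref_params, age_span=(25, 60))
    rel = bmd_relative(traj, 25.0)
    assert rel[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bmd_relative(traj, 20.0)


def test_btm_changes_vanish_at_unperturbed_steady_state(ref_params):
    curve = EstrogenCurve.constant(1.0)
    traj = simulate(ref_params, curve, age_span=(25.0, 45.0))
    for key in ("ctx_change", "p1np_change", "bsap_change"):
        assert np.max(np.abs(traj.observables[key])) < 1e-3


def test_btm_baseline_outside_span_rejected(ref_params):
    traj = simulate(ref_params, age_span=(25, 40))
    with pytest.raises(ValueError):
        btm_observables(traj, ref_params, 50.0)


def test_denosumab_suppresses_ctx_teriparatide_raises_p1np(ref_params):
    reg = make_block_regimen([("denosumab", 60, 0.5, 1.0)], start_age=60)
    traj = simulate(ref_params, regimen=reg, age_span=(59.5, 61.0))
    i = np.argmin(np.abs(traj.times - 60.25))
    assert traj.observables["ctx_change"][i] < 0

    reg = make_block_regimen([("teriparatide", 0.02, 1 / 365, 0.25)], start_age=60)
    traj = simulate(ref_params, regimen=reg, age_span=(59.5, 60.5))
    i = np.argmin(np.abs(traj.times - 60.2))
    assert traj.observables["p1np_change"][i] > 0


def test_denosumab_cessation_rebound(ref_params):
    """Precursor pool accumulates under treatment; osteoclasts overshoot
    their pre-treatment level within two years of the last dose."""
    reg = make_block_regimen([("denosumab", 60, 0.5, 3.0)], start_age=60)
    last_dose = max(ev.time for ev in reg.events)
    traj = simulate(ref_params, regimen=reg, age_span=(55.0, last_dose + 2.0))
    t = traj.times
    oc = traj.column("oc")
    pre_oc = traj.column("pre_oc")
    oc_pre_treatment = oc[t < 60.0].max()
    during = (t >= 60.0) & (t <= last_dose)
    after = t > last_dose
    assert pre_oc[during].max() > 1.0
    assert oc[after].max() > oc_pre_treatment


# ---------------------------------------------------------------------------
# error handling


def test_events_outside_span_rejected(ref_params):
    reg = make_block_regimen([("denosumab", 60, 0.5, 1.0)], start_age=60)
    with pytest.raises(ValueError):
        simulate(ref_params, regimen=reg, age_span=(62, 70))


def test_decreasing_span_rejected(ref_params):
    with pytest.raises(ValueError):
        simulate(ref_params, age_span=(60, 60))
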