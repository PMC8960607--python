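import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocdsim import degradation as dg
from ocdsim.config import DegradationParams, PRESETS, preset
ALL_PRESETS = sorted(PRESETS)


def fresh(layout, params):
    return dg.init_scaffold_state(layout, params)


def advance(state, params, days):
    for _ in range(days):
        state = dg.step(state, params)
    return state


# ---------------------------------------------------------------------------
# Analytic milestone calendar


EXPECTED_MILESTONES = {
    # modality, speed -> (onset_surface, onset_bulk, bulk_complete,
    #                     first_layer, full)
    ("surface_erosion", "fast"): (1, None, None, 13, 25),
    ("surface_erosion", "matched"): (1, None, None, 25, 50),
    ("surface_erosion", "slow"): (1, None, None, 50, 100),
    ("bulk", "fast"): (23, 23, 25, None, 25),
    ("bulk", "matched"): (45, 45, 50, None, 50),
    ("bulk", "slow"): (90, 90, 100, None, 100),
    ("bulk_autocatalytic", "fast"): (23, 12, 13, None, 25),
    ("bulk_autocatalytic", "matched"): (45, 23, 25, None, 50),
    ("bulk_autocatalytic", "slow"): (90, 45, 50, None, 100),
    ("exponential", "fast"): (105, 105, 115, None, 115),
    ("exponential", "slow"): (768, 768, 778, None, 778),
}


@pytest.mark.parametrize("key", ALL_PRESETS, ids=lambda k: f"{k[0]}-{k[1]}")
def test_milestone_calendar(key, layout):
    """Closed-form degradation calendar for every rate preset."""
    exp = EXPECTED_MILESTONES[key]
    m = dg.milestones(PRESETS[key], layout)
    assert (m.erosion_onset_day_surface, m.erosion_onset_day_bulk,
            m.bulk_complete_day, m.first_surface_layer_complete_day,
            m.full_degradation_day) == exp


@pytest.mark.parametrize("key", ALL_PRESETS, ids=lambda k: f"{k[0]}-{k[1]}")
def test_daily_stepping_reproduces_analytic_calendar(key, layout):
    """Oracle equivalence: milestone days observed from the daily-stepped
    state equal the closed-form calendar for every preset."""
    params = PRESETS[key]
    analytic = dg.milestones(params, layout)
    observed = dg.observe_milestones_by_stepping(params, layout)
    assert observed.as_dict() == analytic.as_dict()


def test_zero_rate_reports_never(layout):
    m = dg.milestones(DegradationParams("exponential", k_e=0.0), layout)
    assert m.full_degradation_day is None
    m = dg.milestones(DegradationParams("bulk", k_E=0.0), layout)
    assert m.erosion_onset_day_surface is None


# ---------------------------------------------------------------------------
# Trajectories and closed forms


def test_initial_state(layout):
    s = fresh(layout, preset("bulk", "matched"))
    assert np.all(s.E == 1000.0)
    assert np.all(s.N == 0.5)
    assert not np.any(s.eroding)


def test_linear_bulk_matches_closed_form(layout):
    params = preset("bulk", "slow")
    s = fresh(layout, params)
    for d in range(1, 80):
        s = dg.step(s, params)
        assert np.allclose(s.E, 1000.0 - 10.0 * d)


def test_exponential_matches_closed_form(layout):
    params = preset("exponential", "slow")
    s = fresh(layout, params)
    for d in range(1, 126):
        s = dg.step(s, params)
        assert np.allclose(s.E, 1000.0 * np.exp(-0.003 * d), rtol=1e-14)
    assert round(s.mean_modulus()) == 687


def test_slow_exponential_day125_volume_fraction(layout, lattice):
    params = preset("exponential", "slow")
    s = advance(fresh(layout, params), params, 125)
    assert 100.0 * s.total_fraction(lattice.n_elements) == pytest.approx(15.0)


def test_zero_rate_surface_erosion_is_identity(layout):
    params = DegradationParams("surface_erosion", k_N=0.0)
    s = advance(fresh(layout, params), params, 50)
    assert np.all(s.E == 1000.0) and np.all(s.N == 0.5)


def test_surface_erosion_preserves_interior_until_exposed(layout):
    """Under surface erosion the interior modulus never changes before the
    column is exposed and fully eroded (then it drops straight to zero)."""
    params = preset("surface_erosion", "fast")
    s = fresh(layout, params)
    bulk0 = s.label == dg.BULK
    for _ in range(30):
        s = dg.step(s, params)
        assert np.all((s.E[bulk0] == 1000.0) | s.fully_degraded[bulk0])


def test_surface_erosion_layer_succession_with_carryover(layout):
    params = preset("surface_erosion", "fast")
    s = fresh(layout, params)
    s12 = advance(s, params, 12)
    assert not np.any(s12.fully_degraded)
    s13 = dg.step(s12, params)
    outer = s13.label[~s13.fully_degraded]
    assert np.any(s13.fully_degraded)          # first layer done on day 13
    # the 0.02 overshoot carried into the newly exposed layer
    assert np.allclose(s13.N[~s13.fully_degraded], 0.48)
    s25 = advance(s13, params, 12)
    assert np.all(s25.fully_degraded)          # 2 layers x 12.5 d -> day 25


def test_wrong_modality_raises(layout):
    s = fresh(layout, preset("bulk", "fast"))
    with pytest.raises(dg.ModalityError):
        dg.step_surface_erosion(s, preset("bulk", "fast"))
    with pytest.raises(dg.ModalityError):
        dg.step_bulk(s, preset("surface_erosion", "fast"))


@pytest.mark.parametrize("modality", ["bulk", "bulk_autocatalytic"])
@pytest.mark.parametrize("speed", ["fast", "matched", "slow"])
def test_modulus_and_fraction_vanish_together(modality, speed, layout):
    """Table presets are mutually consistent: E_t and N_t reach zero on
    the same day in every linear bulk preset."""
    params = preset(modality, speed)
    s = fresh(layout, params)
    for _ in range(130):
        prev = s
        s = dg.step(s, params)
        newly = s.fully_degraded & ~prev.fully_degraded
        if np.any(newly):
            assert np.all(s.E[newly] == 0.0) and np.all(s.N[newly] == 0.0)
    assert np.all(s.fully_degraded)


@pytest.mark.parametrize("key", ALL_PRESETS, ids=lambda k: f"{k[0]}-{k[1]}")
def test_monotone_non_increase(key, layout):
    """E_t and N_t never increase, for any element, under any modality."""
    params = PRESETS[key]
    s = fresh(layout, params)
    for _ in range(60):
        nxt = dg.step(s, params)
        assert np.all(nxt.E <= s.E + 1e-12)
        assert np.all(nxt.N <= s.N + 1e-12)
        s = nxt


@settings(max_examples=25, deadline=None, derandomize=True)
@given(k_E=st.floats(1.0, 80.0), k_N=st.floats(0.01, 0.5),
       modality=st.sampled_from(["bulk", "bulk_autocatalytic"]))
def test_monotonicity_and_bounds_for_random_rates(k_E, k_N, modality, layout):
    params = DegradationParams(modality, k_E=k_E, k_N=k_N)
    s = fresh(layout, params)
    for _ in range(40):
        nxt = dg.step(s, params)
        assert np.all(nxt.E <= s.E + 1e-12)
        assert np.all(nxt.N <= s.N + 1e-12)
        assert np.all(nxt.E >= 0.0) and np.all(nxt.N >= 0.0)
        assert np.all(nxt.E[nxt.fully_degraded] == 0.0)
        s = nxt


def test_trajectory_frame(layout, lattice):
    params = preset("exponential", "slow")
    df = dg.trajectory(params, layout, 125, lattice.n_elements)
    assert len(df) == 126
    assert df["volume_fraction_pct"].iloc[0] == pytest.approx(15.0)
    assert round(df["mean_modulus"].iloc[-1]) == 687
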