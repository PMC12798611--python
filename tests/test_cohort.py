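"""Trajectory generator vs its closed-form occupancy oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gadsim import (
    ArmId,
    Conventions,
    Timing,
    apply_overrides,
    draw_trajectory,
    expected_occupancy,
    simulate_arm,
)
from gadsim.cohort import arm_rng, arm_substream_seed, gad_fraction_matrix

ALL_ARMS = list(ArmId)


def enumerate_occupancy(q, p, r, credit, attr_c2=True):
    """Independent oracle: exhaustive enumeration of the discrete outcome
    tree (attrite? x remit cycle 1? x remit cycle 2?) for a two-cycle model,
    with a within-cycle remitter spending ``credit`` of the cycle in GAD."""
    f1 = f2 = remitted = 0.0
    for attrited, w_a in ((True, q), (False, 1 - q)):
        p1 = 0.0 if attrited else p
        for rem1, w_1 in ((True, p1), (False, 1 - p1)):
            if rem1:
                f1 += w_a * w_1 * credit
                remitted += w_a * w_1
                continue
            f1 += w_a * w_1 * 1.0
            p2 = r if (not attrited or attr_c2) else 0.0
            for rem2, w_2 in ((True, p2), (False, 1 - p2)):
                w = w_a * w_1 * w_2
                f2 += w * (credit if rem2 else 1.0)
                remitted += w if rem2 else 0.0
    return f1, f2, remitted


@pytest.mark.parametrize("timing", list(Timing))
@pytest.mark.parametrize("arm", ALL_ARMS)
def test_expected_occupancy_matches_enumeration(params, arm, timing):
    """Closed form == brute-force enumeration over the outcome tree."""
    ap = params.arms[arm]
    occ = expected_occupancy(arm, params, timing)
    f1, f2, rem = enumerate_occupancy(
        ap.attrition_prob, ap.remission_prob_cycle1,
        params.globals.natural_remission_prob, timing.gad_credit)
    assert occ.expected_gad_fraction_by_cycle == pytest.approx((f1, f2), abs=1e-12)
    assert occ.expected_remitted_share == pytest.approx(rem, abs=1e-12)


def test_expected_occupancy_absorbing_attrition_matches_enumeration(params):
    conv = Conventions(attrition_second_cycle_remission=False)
    ap = params.arms[ArmId.GROUP_CBT]
    occ = expected_occupancy(ArmId.GROUP_CBT, params, Timing.UNIFORM, conv)
    f1, f2, rem = enumerate_occupancy(
        ap.attrition_prob, ap.remission_prob_cycle1,
        params.globals.natural_remission_prob, 0.5, attr_c2=False)
    assert occ.expected_gad_fraction_by_cycle == pytest.approx((f1, f2), abs=1e-12)
    assert occ.expected_remitted_share == pytest.approx(rem, abs=1e-12)


def test_expected_occupancy_known_values(params):
    """Hand-derived closed-form spot checks for the base case."""
    none = expected_occupancy(ArmId.NO_TREATMENT, params, Timing.UNIFORM)
    assert none.expected_gad_fraction_by_cycle[0] == pytest.approx(1 - 0.15 / 2)
    dig = expected_occupancy(ArmId.DIGITAL_CBT, params, Timing.UNIFORM)
    share = (1 - 0.16) * 0.60 + (1 - (1 - 0.16) * 0.60) * 0.15
    assert dig.expected_remitted_share == pytest.approx(share)


def test_zero_remission_everywhere_keeps_everyone_in_gad(params):
    p2 = apply_overrides(params, {
        "arms.no_treatment.remission_prob_cycle1": 0.0,
        "globals.natural_remission_prob": 0.0,
    })
    occ = expected_occupancy(ArmId.NO_TREATMENT, p2)
    assert occ.expected_gad_fraction_by_cycle == (1.0, 1.0)
    assert occ.expected_remitted_share == 0.0


def test_certain_remission_trajectory(params):
    p2 = apply_overrides(params, {
        "arms.digital_cbt.remission_prob_cycle1": 1.0,
        "arms.digital_cbt.attrition_prob": 0.0,
    })
    t = draw_trajectory(ArmId.DIGITAL_CBT, p2, arm_rng(0, ArmId.DIGITAL_CBT))
    assert t.remission_time is not None and t.remission_time < 0.5
    assert t.gad_fraction_by_cycle[1] == 0.0


def test_no_remission_trajectory(params):
    p2 = apply_overrides(params, {
        "arms.no_treatment.remission_prob_cycle1": 0.0,
        "globals.natural_remission_prob": 0.0,
    })
    t = draw_trajectory(ArmId.NO_TREATMENT, p2, arm_rng(0, ArmId.NO_TREATMENT))
    assert t.remission_time is None
    assert t.gad_fraction_by_cycle == (1.0, 1.0)


def test_seeded_reproducibility(params):
    a = simulate_arm(ArmId.DIGITAL_CBT, params, seed=7)
    b = simulate_arm(ArmId.DIGITAL_CBT, params, seed=7)
    assert np.array_equal(a.attrited, b.attrited)
    assert np.array_equal(a.attrition_time, b.attrition_time, equal_nan=True)
    assert np.array_equal(a.remission_time, b.remission_time, equal_nan=True)
    c = simulate_arm(ArmId.DIGITAL_CBT, params, seed=8)
    assert not np.array_equal(a.remission_time, c.remission_time, equal_nan=True)


def test_arm_substreams_are_stable_and_distinct(params):
    seeds = {arm: arm_substream_seed(1, arm) for arm in ALL_ARMS}
    assert len(set(seeds.values())) == 5
    assert all(0 <= s < 2**31 for s in seeds.values())
    # same master seed, different arms -> different draws
    a = simulate_arm(ArmId.DIGITAL_CBT, params, seed=1, n=100)
    b = simulate_arm(ArmId.GROUP_CBT, params, seed=1, n=100)
    assert not np.array_equal(a.remission_time, b.remission_time, equal_nan=True)


def test_no_treatment_never_attrites(params):
    s = simulate_arm(ArmId.NO_TREATMENT, params, seed=3)
    assert int(s.attrited.sum()) == 0


@pytest.mark.parametrize(
    "arm,rate",
    [(ArmId.PHARMACOTHERAPY, 0.30), (ArmId.DIGITAL_CBT, 0.16),
     (ArmId.GROUP_CBT, 0.24), (ArmId.INDIVIDUAL_CBT, 0.09)],
)
def test_attrition_share_within_three_binomial_se(params, arm, rate):
    s = simulate_arm(arm, params, seed=11)
    n = s.n
    se = np.sqrt(rate * (1 - rate) / n)
    assert abs(s.attrited.mean() - rate) < 3 * se


def test_natural_remission_share_within_three_binomial_se(params):
    """About 15% of the untreated arm remits during cycle 1."""
    s = simulate_arm(ArmId.NO_TREATMENT, params, seed=5)
    remit_c1 = np.nansum(s.remission_time < 0.5) / s.n
    se = np.sqrt(0.15 * 0.85 / s.n)
    assert abs(remit_c1 - 0.15) < 3 * se


@pytest.mark.parametrize("arm", ALL_ARMS)
def test_monte_carlo_occupancy_matches_oracle(params, arm):
    """MC mean per-cycle GAD fraction within 3 SE of the closed form."""
    s = simulate_arm(arm, params, seed=17)
    F = s.gad_fractions(Timing.UNIFORM)
    occ = expected_occupancy(arm, params, Timing.UNIFORM)
    for k in range(params.globals.n_cycles):
        se = F[:, k].std(ddof=1) / np.sqrt(s.n)
        assert abs(F[:, k].mean() - occ.expected_gad_fraction_by_cycle[k]) < 3 * se
    share = 1 - np.isnan(s.remission_time).mean()
    p = occ.expected_remitted_share
    assert abs(share - p) < 3 * np.sqrt(p * (1 - p) / s.n)


@pytest.mark.parametrize("timing", list(Timing))
@pytest.mark.parametrize("arm", ALL_ARMS)
def test_absorbing_remission(params, arm, timing):
    """Occupancy never increases across cycles; once partial, then zero."""
    F = simulate_arm(arm, params, seed=23, n=5000).gad_fractions(timing)
    assert (np.diff(F, axis=1) <= 1e-12).all()
    partial = F[:, 0] < 1.0
    assert (F[partial, 1] == 0.0).all()


def test_attriters_cannot_remit_in_cycle_one(params):
    s = simulate_arm(ArmId.GROUP_CBT, params, seed=29)
    t = s.remission_time[s.attrited]
    assert np.all(np.isnan(t) | (t >= 0.5))


def test_absorbing_attrition_convention(params):
    conv = Conventions(attrition_second_cycle_remission=False)
    s = simulate_arm(ArmId.GROUP_CBT, params, seed=31, conventions=conv)
    assert np.isnan(s.remission_time[s.attrited]).all()


def test_raising_remission_never_shrinks_remitted_time(params):
    """Common random numbers: remission time is monotone in the hazard."""
    lo = simulate_arm(ArmId.DIGITAL_CBT, params, seed=41)
    p2 = apply_overrides(params, {"arms.digital_cbt.remission_prob_cycle1": 0.9})
    hi = simulate_arm(ArmId.DIGITAL_CBT, p2, seed=41)
    t_lo = np.nan_to_num(lo.remission_time, nan=1.0)
    t_hi = np.nan_to_num(hi.remission_time, nan=1.0)
    assert (t_hi <= t_lo + 1e-12).all()


def test_trajectory_frame_shape(params):
    df = simulate_arm(ArmId.DIGITAL_CBT, params, seed=1, n=50).to_frame()
    assert list(df.columns) == ["person_id", "arm", "attrited", "attrition_time",
                                "remission_time", "gad_fraction_c1", "gad_fraction_c2"]
    assert len(df) == 50


@given(
    t=st.one_of(st.none(), st.floats(min_value=0, max_value=1, exclude_max=True)),
    timing=st.sampled_from(list(Timing)),
)
def test_gad_fraction_invariants(t, timing):
    """For any remission time: fractions in [0,1], non-increasing, and all
    ones when remission never happens."""
    arr = np.array([np.nan if t is None else t])
    F = gad_fraction_matrix(arr, 0.5, 2, timing)[0]
    assert ((0.0 <= F) & (F <= 1.0)).all()
    assert F[1] <= F[0] + 1e-12
    if t is None:
        assert (F == 1.0).all()
    elif timing is Timing.UNIFORM and t < 0.5:
        assert F[0] == pytest.approx(t / 0.5)
        assert F[1] == 0.0
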