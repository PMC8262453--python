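"""Circular descriptives and the Watson-Williams test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from tempoclust.circular import (
    _watson_williams_F,
    angle_to_clock,
    circ_anova,
    circ_mean,
    circ_posthoc,
    holm_adjust,
    kappa_from_rbar,
    to_angles,
)


def test_hour_to_angle_definition():
    s = to_angles([0, 6, 12])
    np.testing.assert_allclose(s.angles, [0.0, np.pi / 2, np.pi])


def test_out_of_range_hour_rejected():
    with pytest.raises(ValueError):
        to_angles([24])


def test_wraparound_mean_is_midnight():
    mu, rbar = circ_mean(to_angles([23, 1]).angles)
    assert mu == pytest.approx(0.0, abs=1e-12)
    assert angle_to_clock(mu) == "00:00"


def test_identical_angles_full_concentration():
    mu, rbar = circ_mean([1.3, 1.3, 1.3])
    assert mu == pytest.approx(1.3)
    assert rbar == pytest.approx(1.0)


def test_uniform_four_points_undefined_mean():
    mu, rbar = circ_mean([0, np.pi / 2, np.pi, 3 * np.pi / 2])
    assert rbar == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(mu)


def test_circ_mean_matches_vector_sum(rng):
    a = rng.uniform(0, 2 * np.pi, 200)
    mu, rbar = circ_mean(a)
    # brute-force resultant vector
    vx, vy = np.cos(a).sum(), np.sin(a).sum()
    assert mu == pytest.approx(np.arctan2(vy, vx) % (2 * np.pi))
    assert rbar == pytest.approx(np.hypot(vx, vy) / a.size)


def test_circ_mean_agrees_with_scipy(rng):
    a = rng.vonmises(2.0, 3.0, 500) % (2 * np.pi)
    mu, _ = circ_mean(a)
    assert mu == pytest.approx(stats.circmean(a), abs=1e-10)


@settings(max_examples=30, deadline=None)
@given(st.floats(0.05, 0.95))
def test_kappa_inversion_roundtrip(rbar):
    k = kappa_from_rbar(rbar)
    a_of_k = special.i1e(k) / special.i0e(k)
    assert abs(a_of_k - rbar) < 1e-6


def test_kappa_zero_at_zero_rbar():
    assert kappa_from_rbar(0.0) == 0.0


def test_rotation_invariance(rng):
    groups = [rng.vonmises(0.5, 4.0, 40) % (2 * np.pi) for _ in range(3)]
    r1 = circ_anova(groups)
    shift = 1.234
    r2 = circ_anova([(g + shift) % (2 * np.pi) for g in groups])
    assert r2.F == pytest.approx(r1.F, rel=1e-9)
    assert r2.p == pytest.approx(r1.p, rel=1e-9)
    for g1, g2 in zip(r1.groups, r2.groups):
        assert (g2.mean_direction - g1.mean_direction) % (2 * np.pi) == pytest.approx(
            shift, abs=1e-9
        )
        assert g2.rbar == pytest.approx(g1.rbar, rel=1e-12)


def test_separated_groups_detected(rng):
    a = rng.vonmises(0.0, 5.0, 100) % (2 * np.pi)
    b = rng.vonmises(np.pi / 2, 5.0, 100) % (2 * np.pi)
    r = circ_anova([a, b])
    assert r.p < 1e-4


def test_f_p_matches_permutation_oracle(rng):
    a = rng.vonmises(0.3, 5.0, 15) % (2 * np.pi)
    b = rng.vonmises(1.0, 5.0, 15) % (2 * np.pi)
    res = circ_anova([a, b])
    pool = np.concatenate([a, b])
    count = 0
    B = 2000
    for _ in range(B):
        p = rng.permutation(pool)
        F, *_ = _watson_williams_F([p[:15], p[15:]])
        count += F >= res.F
    perm_p = count / B
    mc_err = 3 * np.sqrt(max(perm_p * (1 - perm_p), 1e-4) / B)
    assert abs(res.p - perm_p) <= mc_err + 0.02


def test_low_concentration_flagged(rng):
    groups = [rng.uniform(0, 2 * np.pi, 30) for _ in range(2)]
    with pytest.warns(UserWarning, match="dubious"):
        r = circ_anova(groups)
    assert r.low_concentration_warning


def test_posthoc_two_groups_holm_equals_raw(rng):
    groups = [rng.vonmises(0.0, 5.0, 30) % (2 * np.pi) for _ in range(2)]
    table = circ_posthoc(groups)
    assert len(table) == 1
    assert table[0]["p_holm"] == pytest.approx(table[0]["p_raw"])


def test_holm_monotone_and_bounded(rng):
    p = rng.uniform(0, 1, 10)
    adj = holm_adjust(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_posthoc_family_error_under_null(rng):
    # 4 identical von Mises groups: expected fraction of Holm-significant
    # replicates stays near the familywise alpha
    hits = 0
    reps = 300
    for _ in range(reps):
        groups = [rng.vonmises(1.0, 5.0, 30) % (2 * np.pi) for _ in range(4)]
        table = circ_posthoc(groups)
        hits += any(row["significant"] for row in table)
    assert hits / reps < 0.11


def test_clock_rendering():
    assert angle_to_clock(np.pi) == "12:00"
    assert angle_to_clock(2 * np.pi * 5.5 / 24) == "05:30"
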