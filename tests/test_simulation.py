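import math

import numpy as np
import pytest

import expectmon as em
from expectmon.simulation import ErrorDist, SimDesign


def _design(**kw):
    base = dict(
        model=em.gompertz2_model(),
        beta0=(10.0, 5.0),
        m=40,
        horizon_rule="fixed10",
        k0_rule="none",
        dist=ErrorDist("gaussian", 0.0, 1.0),
        n_reps=10,
        seed=123,
    )
    base.update(kw)
    return SimDesign(**base)


# ---------------------------------------------------------------------------
# error distributions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dist",
    [ErrorDist("gaussian", 1.0, 1.0), ErrorDist("laplace", 0.0, 1.0), ErrorDist("laplace", -2.0, 4.0)],
)
def test_error_dist_moments(dist):
    rng = np.random.default_rng(0)
    s = dist.sample(rng, 200_000)
    assert s.mean() == pytest.approx(dist.mean, abs=0.02 * max(1.0, abs(dist.mean)) + 0.02)
    assert s.var() == pytest.approx(dist.variance, rel=0.03)


def test_error_dist_validation():
    with pytest.raises(ValueError):
        ErrorDist("cauchy", 0.0, 1.0)
    with pytest.raises(ValueError):
        ErrorDist("gaussian", 0.0, -1.0)


# ---------------------------------------------------------------------------
# design bookkeeping
# ---------------------------------------------------------------------------

def test_horizon_rules():
    assert _design(m=200, horizon_rule="fixed10").T_m == 10
    assert _design(m=200, horizon_rule="half_m").T_m == 100
    assert _design(m=200, horizon_rule="m_log_m").T_m == int(200 * math.log(200))
    assert _design(m=200, horizon_rule="m_log_m").open_end
    assert not _design(m=200, horizon_rule="half_m").open_end


def test_changepoint_placement_rules():
    d = _design(m=200, horizon_rule="half_m", k0_rule="immediate", beta1=(10.0, 10.0))
    assert d.k0 == 0  # every online observation is already post-change
    d = _design(m=200, horizon_rule="half_m", k0_rule="midpoint", beta1=(10.0, 10.0))
    assert d.k0 == 50  # first changed observation is online index 51


def test_design_validation():
    with pytest.raises(ValueError):
        _design(k0_rule="immediate")  # beta1 missing
    with pytest.raises(ValueError):
        _design(beta1=(1.0, 1.0))  # beta1 without a changepoint rule
    with pytest.raises(ValueError):
        _design(horizon_rule="weekly")
    with pytest.raises(ValueError):
        _design(beta0=(1.0,))


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def test_gen_dataset_is_deterministic_in_the_seed():
    d = _design()
    a = em.gen_dataset(d, 99)
    b = em.gen_dataset(d, 99)
    for u, v in zip(a, b):
        assert np.array_equal(u, v)
    c = em.gen_dataset(d, 100)
    assert not np.array_equal(a[1], c[1])


def test_gen_dataset_noiseless_null_reproduces_the_curve():
    d = _design(dist=ErrorDist("gaussian", 0.0, 0.0))
    Xh, Yh, Xo, Yo = em.gen_dataset(d, 1)
    assert np.allclose(Yh, d.model.predict(Xh, d.beta0))
    assert np.allclose(Yo, d.model.predict(Xo, d.beta0))


def test_gen_dataset_midpoint_switches_parameters_exactly():
    d = _design(
        m=30,
        horizon_rule="half_m",
        k0_rule="midpoint",
        beta1=(10.0, 10.0),
        dist=ErrorDist("gaussian", 0.0, 0.0),
    )
    Xh, Yh, Xo, Yo = em.gen_dataset(d, 5)
    T, k0 = d.T_m, d.k0
    assert np.allclose(Yo[:k0], d.model.predict(Xo[:k0], d.beta0))
    assert np.allclose(Yo[k0:], d.model.predict(Xo[k0:], d.beta1))
    # the change is real: the two parameterisations differ on these points
    assert not np.allclose(
        d.model.predict(Xo[k0:], d.beta0), d.model.predict(Xo[k0:], d.beta1)
    )


def test_equispaced_design_flag():
    d = _design(design="equispaced")
    Xh, *_ = em.gen_dataset(d, 3)
    assert np.allclose(Xh[:, 0], np.arange(1, 41) / 41)


# ---------------------------------------------------------------------------
# experiment drivers (threshold overridden so no limit simulation runs)
# ---------------------------------------------------------------------------

def test_level_experiment_never_rejects_at_infinite_threshold():
    res = em.run_level_experiment(_design(threshold=math.inf, n_reps=8))
    assert res.rejection_rate == 0.0
    assert res.n_valid == 8
    assert res.mean_location is None


def test_power_reduces_to_level_when_beta1_equals_beta0():
    level = em.run_level_experiment(_design(threshold=0.9, n_reps=12))
    power = em.run_power_experiment(
        _design(threshold=0.9, n_reps=12, k0_rule="immediate", beta1=(10.0, 5.0))
    )
    assert power.rejection_rate == level.rejection_rate


def test_noiseless_large_shift_detected_at_first_observation():
    res = em.run_power_experiment(
        _design(
            m=30,
            k0_rule="immediate",
            beta1=(10.0, 12.0),
            dist=ErrorDist("gaussian", 0.0, 0.0),
            threshold=3.0,
            n_reps=5,
        )
    )
    assert res.rejection_rate == 1.0
    # detection essentially immediate; an occasional first draw lands where
    # the two curves coincide, postponing detection by one observation
    assert res.median_location == 0.0
    assert res.mean_location < 0.15


def test_midpoint_rule_discards_first_half_detections():
    # a threshold of ~0 would be crossed at k=1, but those count as false alarms
    res = em.run_power_experiment(
        _design(
            m=30,
            horizon_rule="half_m",
            k0_rule="midpoint",
            beta1=(10.0, 10.0),
            threshold=1e-9,
            n_reps=6,
        )
    )
    T = 15
    assert res.rejection_rate == 1.0
    assert res.mean_location == pytest.approx((T // 2 + 1 - 1) / (T - 1))
    assert res.mean_location >= 0.5  # never attributed to the first half


def test_driver_guards():
    with pytest.raises(ValueError):
        em.run_power_experiment(_design(threshold=1.0))
    with pytest.raises(ValueError):
        em.run_level_experiment(
            _design(threshold=1.0, k0_rule="immediate", beta1=(1.0, 1.0))
        )
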