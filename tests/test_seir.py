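"""Tests for the network SEIR simulator and scenario machinery."""

import dataclasses

import numpy as np
import pytest

from behavepi import network, seir
from behavepi.seir import E, I, R, S, Scenario, SEIRParams

from conftest import two_node_graph


# ------------------------------------------------------------ endogenous law


def test_endogenous_law_three_fold_at_reference_incidence():
    assert seir.endogenous_q(0.10) == pytest.approx(1.0 / 3.0, abs=1e-15)
    assert seir.endogenous_q(0.0) == 1.0
    assert seir.endogenous_q(0.20) == pytest.approx(1.0 / 9.0, rel=1e-12)


def test_endogenous_law_monotone_and_bounded():
    rho = np.linspace(0.0, 1.0, 101)
    q = np.array([seir.endogenous_q(r) for r in rho])
    assert np.all(np.diff(q) < 0)
    assert np.all((q > 0) & (q <= 1))


def test_endogenous_law_domain_errors():
    with pytest.raises(ValueError):
        seir.endogenous_q(-0.1)
    with pytest.raises(ValueError):
        seir.endogenous_q(0.5, fold=1.0)


# ------------------------------------------------------------ initialization


def test_initialize_seeds_exact_count(small_graph):
    params = SEIRParams(initial_infected_frac=0.002, seed=1)
    g1000 = network.generate_graph(1000, seed=10)
    state = seir.initialize(g1000, params, Scenario(kind="none"))
    counts = state.counts()
    assert counts[I] == 2  # ceil(0.002 * 1000)
    assert counts[S] == 998
    assert np.all(state.q == 1.0)


def test_initialize_immobilization_assignment():
    g = network.generate_graph(1000, seed=10)
    params = SEIRParams(seed=2)
    state = seir.initialize(g, params, Scenario(kind="random_immobilization", p=0.3))
    assert np.sum(state.q == 0.1) == 300
    assert np.sum(state.q == 1.0) == 700


def test_initialize_warns_below_one_expected_seed():
    g = network.generate_graph(100, seed=10)
    params = SEIRParams(initial_infected_frac=0.002, seed=3)
    with pytest.warns(UserWarning):
        state = seir.initialize(g, params, Scenario(kind="none"))
    assert state.counts()[I] == 1  # rounded up to a single seed


# ------------------------------------------------------------ single-step law


def test_single_edge_infection_probability_matches_bernoulli():
    g = two_node_graph()
    params = SEIRParams(beta_trans=0.3, sigma=0.5, gamma=0.5)
    rng = np.random.default_rng(99)
    hits = 0
    trials = 10_000
    for _ in range(trials):
        state = seir.EpidemicState(
            compartments=np.array([I, S], dtype=np.int8),
            q=np.ones(2),
            t=0,
            rng=rng,
        )
        seir.step(state, g, params, Scenario(kind="none"))
        hits += state.compartments[1] in (E, I)
    # exact Bernoulli(0.3): three-sigma binomial band
    se = np.sqrt(0.3 * 0.7 / trials)
    assert abs(hits / trials - 0.3) < 3 * se


def test_isolated_nodes_never_infected(small_graph):
    params = SEIRParams(horizon=60, n_realizations=2, seed=5)
    curve = seir.run(small_graph, params, Scenario(kind="uniform", q_uniform=0.0))
    # no new exposures: final recovered equals the initial seeds
    assert curve.attack_rate == pytest.approx(
        np.ceil(0.002 * small_graph.n_nodes) / small_graph.n_nodes
    )
    assert np.all(curve.e == 0.0)


def test_no_transmission_without_infectivity(small_graph):
    params = SEIRParams(beta_trans=0.0, horizon=60, n_realizations=2, seed=5)
    curve = seir.run(small_graph, params, Scenario(kind="none"))
    assert curve.attack_rate == pytest.approx(
        np.ceil(0.002 * small_graph.n_nodes) / small_graph.n_nodes
    )


# ------------------------------------------------------------ invariants


def test_compartments_conserved_and_monotone_per_realization(small_graph):
    params = SEIRParams(horizon=120, seed=11)
    rng = np.random.default_rng(11)
    state = seir.initialize(small_graph, params, Scenario(kind="endogenous"), rng=rng)
    n = small_graph.n_nodes
    prev_s, prev_r = state.counts()[S], state.counts()[R]
    for _ in range(120):
        seir.step(state, small_graph, params, Scenario(kind="endogenous"))
        counts = state.counts()
        assert counts.sum() == n
        assert counts[S] <= prev_s
        assert counts[R] >= prev_r
        assert np.all((state.q >= 0) & (state.q <= 1))
        prev_s, prev_r = counts[S], counts[R]


def test_run_is_bitwise_reproducible(small_graph, fast_params):
    c1 = seir.run(small_graph, fast_params, Scenario(kind="endogenous"))
    c2 = seir.run(small_graph, fast_params, Scenario(kind="endogenous"))
    for attr in ("s", "e", "i", "r", "q_mean"):
        assert np.array_equal(getattr(c1, attr), getattr(c2, attr))
    assert c1.peak_infected_fraction == c2.peak_infected_fraction


def test_unrestrained_equals_uniform_full_mobility(small_graph, fast_params):
    c_none = seir.run(small_graph, fast_params, Scenario(kind="none"))
    c_q1 = seir.run(small_graph, fast_params, Scenario(kind="uniform", q_uniform=1.0))
    assert np.array_equal(c_none.i, c_q1.i)
    assert np.array_equal(c_none.r, c_q1.r)


def test_curve_fractions_sum_to_one(small_graph, fast_params):
    c = seir.run(small_graph, fast_params, Scenario(kind="none"))
    total = c.s + c.e + c.i + c.r
    assert np.allclose(total, 1.0)
    assert np.all(np.diff(c.r) >= -1e-12)
    assert np.all(np.diff(c.s) <= 1e-12)


def test_endogenous_contact_rate_mirrors_infection_curve(small_graph):
    params = SEIRParams(horizon=150, n_realizations=10, seed=13)
    c = seir.run(small_graph, params, Scenario(kind="endogenous"))
    t_qmin = int(np.argmin(c.q_mean))
    assert abs(t_qmin - c.peak_time) <= 5  # contacts bottom out around the peak
    assert c.q_mean[0] > c.q_mean[t_qmin]
    assert c.q_mean[-1] > c.q_mean[t_qmin]  # contacts recover as infection fades


def test_endogenous_flattens_the_curve(small_graph):
    params = SEIRParams(horizon=150, n_realizations=12, seed=17)
    c_none = seir.run(small_graph, params, Scenario(kind="none"))
    c_endo = seir.run(small_graph, params, Scenario(kind="endogenous"))
    # scenarios share realization seeds: compare peaks pairwise
    diffs = c_none.realization_peaks - c_endo.realization_peaks
    gap = diffs.mean()
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert gap > 2 * se
    assert c_endo.peak_infected_fraction < c_none.peak_infected_fraction


def test_per_status_endogenous_law_reduces_ill_contacts_more(small_graph):
    params = SEIRParams(horizon=80, n_realizations=1, seed=19)
    scen = Scenario(kind="endogenous", incidence_scale=0.15, incidence_scale_ill=0.09)
    rng = np.random.default_rng(19)
    state = seir.initialize(small_graph, params, scen, rng=rng)
    for _ in range(40):
        seir.step(state, small_graph, params, scen)
    # refresh q from the current compartments, then compare by status
    seir._update_endogenous_q(state, scen)
    ill = state.compartments == I
    assert state.rho > 0 and ill.any() and (~ill).any()
    assert state.q[ill].max() < state.q[~ill].min()


# ------------------------------------------------------------ sweeps and matching


def test_uniform_sweep_edges_and_monotonicity(small_graph):
    params = SEIRParams(horizon=150, n_realizations=10, seed=23)
    qs = [1.0, 0.7, 0.4, 0.1]
    sweep = seir.sweep_uniform(small_graph, params, qs)
    peaks = [c.peak_infected_fraction for c in sweep]
    ses = [c.peak_se for c in sweep]
    for k in range(len(qs) - 1):
        assert peaks[k + 1] <= peaks[k] + 2 * (ses[k] + ses[k + 1])
    c_none = seir.run(small_graph, params, Scenario(kind="none"))
    assert np.array_equal(sweep[0].i, c_none.i)  # q = 1 is the unrestrained model


def test_immobilization_sweep_edges(small_graph):
    params = SEIRParams(horizon=150, n_realizations=10, seed=29)
    sweep = seir.sweep_immobilization(small_graph, params, [0.0, 0.5, 1.0])
    c_none = seir.run(small_graph, params, Scenario(kind="none"))
    assert np.array_equal(sweep[0].i, c_none.i)  # p = 0: nobody immobilized
    # p = 1 assigns q = 0.1 to everyone: same in distribution as uniform q = 0.1
    c_q01 = seir.run(small_graph, params, Scenario(kind="uniform", q_uniform=0.1))
    state_p1 = seir.initialize(
        small_graph, params, Scenario(kind="random_immobilization", p=1.0)
    )
    assert np.all(state_p1.q == 0.1)
    gap = abs(sweep[2].peak_infected_fraction - c_q01.peak_infected_fraction)
    assert gap <= 3 * (sweep[2].peak_se + c_q01.peak_se) + 1e-9


def synthetic_curve(kind, peak, **kw):
    scen = Scenario(kind=kind, **kw)
    t = np.arange(3)
    z = np.zeros(3)
    return seir.EpidemicCurve(
        scenario=scen,
        t=t,
        s=z,
        e=z,
        i=np.array([0.0, peak, 0.0]),
        r=z,
        se_i=z,
        q_mean=z,
        peak_infected_fraction=peak,
        peak_time=1,
        attack_rate=peak,
        n_nodes=100,
        n_realizations=1,
        realization_peaks=np.array([peak]),
        realization_attacks=np.array([peak]),
    )


def test_match_threshold_exact_and_interpolated():
    sweep = [
        synthetic_curve("uniform", pk, q_uniform=1.0 - x)
        for x, pk in [(0.0, 0.3), (0.2, 0.2), (0.4, 0.1), (0.6, 0.05)]
    ]
    endo = synthetic_curve("endogenous", 0.1)
    assert seir.match_threshold(endo, sweep) == pytest.approx(0.4)
    endo = synthetic_curve("endogenous", 0.15)
    assert seir.match_threshold(endo, sweep) == pytest.approx(0.3)
    endo = synthetic_curve("endogenous", 0.01)
    assert seir.match_threshold(endo, sweep) is None


def test_match_threshold_self_match():
    sweep = [
        synthetic_curve("uniform", pk, q_uniform=1.0 - x)
        for x, pk in [(0.0, 0.3), (0.5, 0.12), (1.0, 0.0)]
    ]
    endo = synthetic_curve("endogenous", 0.12)
    # a sweep entry with exactly the endogenous peak matches at its own intensity
    assert seir.match_threshold(endo, sweep) == pytest.approx(0.5)


def test_curve_and_sweep_export_layout(small_graph, fast_params):
    c = seir.run(small_graph, fast_params, Scenario(kind="endogenous"))
    frame = seir.curve_to_frame(c)
    assert list(frame.columns) == ["t", "s", "e", "i", "r", "se_i", "q_t", "scenario"]
    sweep = seir.sweep_uniform(small_graph, fast_params, [1.0, 0.5])
    summary = seir.sweep_summary_frame(sweep)
    assert list(summary["intensity"]) == [0.0, 0.5]
    assert {"peak", "peak_time", "attack_rate"} <= set(summary.columns)
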