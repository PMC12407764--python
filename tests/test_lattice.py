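"""Unit and property tests of the excitable-lattice simulator."""

import numpy as np
import pytest
import scipy.sparse as sp

import critperturb as cp
from critperturb.lattice import (ACTIVE, REST, REFRACTORY, LatticeNetwork,
                                 SimState)


# ---------------------------------------------------------------------------
# construction


def test_full_connectivity_on_tiny_torus():
    net = cp.build_lattice(side=2, spacing_um=12, gauss_amp=1.0,
                           gauss_scale_um=1e9, exp_amp=0.0, seed=0)
    assert net.k_bar == 3.0  # every ordered pair connected, no self-edges
    assert net.adjacency.diagonal().sum() == 0


def test_empty_adjacency_and_branching_error():
    net = cp.build_lattice(side=5, gauss_amp=0.0, exp_amp=0.0, seed=0)
    assert net.k_bar == 0.0
    assert cp.set_branching(net, 0.0).p_trans == 0.0
    with pytest.raises(cp.ParameterError):
        cp.set_branching(net, 1.0)


def test_probability_overflow_raises():
    with pytest.raises(cp.ParameterError):
        cp.build_lattice(side=10, gauss_amp=0.9, exp_amp=0.5, seed=0)


def test_measured_degree_matches_offset_sum_oracle():
    """Mean out-degree equals the analytic sum of Pconn over torus offsets."""
    side, seed = 48, 11
    net = cp.build_lattice(side=side, seed=seed)
    expected = cp.expected_out_degree(side=side)
    # each ordered pair is Bernoulli(p): the mean degree has known variance
    p, _ = cp.lattice._offset_probabilities(side, 12.0, 0.05, 100.0, 0.03,
                                            290.0)
    sd = np.sqrt((p * (1 - p)).sum() / side**2)
    assert abs(net.k_bar - expected) < 5 * sd


def test_branching_parameter_arithmetic(small_net):
    net = cp.set_branching(small_net, 1.0066)
    assert net.p_trans == pytest.approx(1.0066 / small_net.k_bar)
    # printed-value arithmetic: sigma/k_bar at k_bar = 43
    assert 1.0066 / 43 == pytest.approx(0.02341, abs=5e-6)
    with pytest.raises(cp.ParameterError):
        cp.set_branching(small_net, 2 * small_net.k_bar)


def test_fov_is_central_block():
    net = cp.build_lattice(side=50, gauss_amp=0.0, exp_amp=0.0, seed=0)
    fov = net.fov_indices
    assert len(fov) == 38 * 38
    rows, cols = fov // 50, fov % 50
    assert rows.min() == cols.min() == 6
    assert rows.max() == cols.max() == 43


# ---------------------------------------------------------------------------
# single-step semantics (NumPy reference)


def _chain_net(n, p_trans):
    adj = sp.csr_matrix(np.eye(n, k=1, dtype=np.int8))
    side = int(np.sqrt(n))
    assert side * side == n
    return LatticeNetwork(side=side, spacing_um=12.0, adjacency=adj,
                          k_bar=adj.nnz / n, rng_seed=0, sigma=None,
                          p_trans=p_trans)


def test_quiet_state_is_absorbing(small_net):
    net = cp.set_branching(small_net, 0.8)
    run = cp.run_lattice(net, 50, p_poiss=0.0, seed=1)
    assert run.active_counts.sum() == 0


def test_deterministic_transmission_reaches_all_out_neighbours():
    net = cp.build_lattice(side=4, gauss_amp=1.0, gauss_scale_um=30.0,
                           exp_amp=0.0, seed=2)
    net = cp.lattice.replace(net, p_trans=1.0)
    sim = SimState.resting(net.n_units)
    sim.state[5] = ACTIVE
    out_nb = net.adjacency.indices[net.adjacency.indptr[5]:
                                   net.adjacency.indptr[6]]
    new, activated = cp.step(net, sim, np.random.default_rng(0))
    assert set(activated) == set(out_nb)
    assert new.state[5] == REFRACTORY


def test_state_conservation_and_refractory_cycle():
    net = _chain_net(16, p_trans=0.0)
    sim = SimState.resting(16)
    sim.state[[0, 3]] = ACTIVE
    rng = np.random.default_rng(0)
    for _ in range(5):
        counts = [np.sum(sim.state == s) for s in (REST, ACTIVE, REFRACTORY)]
        assert sum(counts) == 16
        sim, _ = cp.step(net, sim, rng)
    # with no drive the two initial units cycled active->refractory->rest
    assert np.all(sim.state == REST)


def test_sigma0_closed_form_rate(small_net):
    """Long-run firing rate matches the isolated-unit Markov chain."""
    net = cp.set_branching(small_net, 0.0)
    q = 0.02
    expected = cp.closed_form_rate_sigma0(q)
    rates = []
    for s in range(4):
        run = cp.run_lattice(net, 12000, p_poiss=q, seed=100 + s)
        rates.append(run.active_counts[2000:].mean() / net.n_units)
    se = np.std(rates, ddof=1) / 2
    assert abs(np.mean(rates) - expected) < 3 * max(se, 1e-5)


def test_seed_determinism(small_net):
    net = cp.set_branching(small_net, 0.9)
    kw = dict(p_poiss=1e-4, seed=42, record_units=net.fov_indices)
    a = cp.run_lattice(net, 3000, **kw)
    b = cp.run_lattice(net, 3000, **kw)
    assert np.array_equal(a.active_counts, b.active_counts)
    assert np.array_equal(a.ev_step, b.ev_step)
    assert np.array_equal(a.ev_channel, b.ev_channel)


def test_activity_monotone_in_drive_and_branching():
    net = cp.build_lattice(side=60, seed=3)

    def rate(sigma, q, seed):
        n = cp.set_branching(net, sigma)
        run = cp.run_lattice(n, 10000, p_poiss=q, seed=seed)
        return run.active_counts[2000:].mean()

    drives = [1e-5, 1e-4, 1e-3]
    r = [rate(0.8, q, 9) for q in drives]
    assert r[0] < r[1] < r[2]
    assert rate(0.5, 1e-4, 9) < rate(0.95, 1e-4, 9)


# ---------------------------------------------------------------------------
# drive calibration


def test_calibration_inverts_sigma0_closed_form(small_net):
    net = cp.set_branching(small_net, 0.0)
    q0 = 0.005
    target = cp.rate_per_frame(cp.closed_form_rate_sigma0(q0))
    q = cp.calibrate_poisson_drive(net, target, tol=0.05, steps=8000,
                                   burn_in=1000, seed=5)
    assert q == pytest.approx(q0, rel=0.15)


def test_calibration_zero_target(small_net):
    assert cp.calibrate_poisson_drive(small_net, 0.0) == 0.0


def test_calibration_infeasible_when_supercritical(small_net):
    net = cp.set_branching(small_net, 1.3)
    with pytest.raises(cp.CalibrationInfeasibleError):
        cp.calibrate_poisson_drive(net, 1e-5, steps=4000, burn_in=1000,
                                   seed=6)


# ---------------------------------------------------------------------------
# frame binning


def test_bin_to_frames_examples():
    raster = np.zeros((1, 33), dtype=int)
    raster[0, 13] = 1
    counts = cp.bin_to_frames(raster)
    assert counts.shape == (1, 3)
    assert counts[0].tolist() == [0, 1, 0]
    counts2, onset_frames = cp.bin_to_frames(raster, onset_steps=[22])
    assert onset_frames.tolist() == [2]
    with pytest.raises(cp.ParameterError):
        cp.bin_to_frames(raster, frame_ms=21)


def test_bin_to_frames_conserves_counts():
    rng = np.random.default_rng(0)
    raster = rng.integers(0, 2, size=(5, 44))
    counts = cp.bin_to_frames(raster)
    assert counts.sum() == raster.sum()


# ---------------------------------------------------------------------------
# stimulation protocol


def test_protocol_fully_driven_tc_spikes_every_third_step():
    # sigma = 0, no drive, p_stim = 1: with the 1-step refractory period a
    # unit is shielded for two activation phases, so it fires every 3rd step
    net = cp.build_lattice(side=40, gauss_amp=0.0, exp_amp=0.0, seed=0)
    net = cp.set_branching(net, 0.0)
    tc = int(net.fov_indices[0])
    proto = cp.StimProtocol([tc], stim_steps=50, iti_steps=100,
                            trials_per_tc=2, p_stim=1.0)
    run = cp.run_protocol(net, proto, p_poiss=0.0, seed=0,
                          burn_in_steps=200)
    rec = run.to_recording()
    ch = np.searchsorted(run.fov_units, tc)
    for onset in run.trials["onset_step"]:
        spikes = run.ev_step[(run.ev_channel == ch)
                             & (run.ev_step >= onset)
                             & (run.ev_step < onset + 50)]
        assert len(spikes) == 17
        assert np.all(np.diff(spikes) == 3)
    assert rec.counts.sum() == len(run.ev_step)


def test_protocol_trial_spacing_and_empty_protocol():
    net = cp.build_lattice(side=40, gauss_amp=0.0, exp_amp=0.0, seed=0)
    net = cp.set_branching(net, 0.0)
    tcs = net.fov_indices[:2]
    proto = cp.StimProtocol(tcs, iti_steps=1000, trials_per_tc=3, p_stim=0.5)
    units, onsets = proto.schedule(start_step=0)
    assert np.all(np.diff(onsets) >= 1050)
    empty = cp.StimProtocol(tcs, trials_per_tc=0, p_stim=0.5)
    run = cp.run_protocol(net, empty, p_poiss=0.0, seed=0)
    assert len(run.trials) == 0


def test_protocol_rejects_tc_outside_fov():
    net = cp.build_lattice(side=40, gauss_amp=0.0, exp_amp=0.0, seed=0)
    proto = cp.StimProtocol([0], p_stim=0.5)  # corner unit, not in the block
    with pytest.raises(cp.ParameterError):
        cp.run_protocol(net, proto, p_poiss=0.0, seed=0)


def test_stim_drive_calibration(small_net):
    net = cp.set_branching(small_net, 0.0)
    tcs = net.fov_indices[:2]
    p = cp.calibrate_stim_drive(net, 0.0, tcs, target_count=2.5, seed=1)
    # sigma = 0 closed form: 50 driven steps at rate q/(1+2q)
    q_pred = 2.5 / (50 - 2 * 2.5)  # drive lasts 50 of the 66 window steps
    assert p == pytest.approx(q_pred, rel=0.2)


# ---------------------------------------------------------------------------
# output strength


def brute_force_walk_strength(adj_dense, p_trans, max_order=5):
    """Exact enumeration of directed walks of length <= max_order."""
    n = adj_dense.shape[0]
    out = np.zeros(n)
    for start in range(n):
        frontier = {start: 1.0}
        for _ in range(max_order):
            nxt = {}
            for node, w in frontier.items():
                for j in range(n):
                    if adj_dense[node, j]:
                        nxt[j] = nxt.get(j, 0.0) + w * p_trans
            out[start] += sum(nxt.values())
            frontier = nxt
    return out


def _net_from_dense(a, p_trans):
    n = a.shape[0]
    return LatticeNetwork(side=1, spacing_um=1.0,
                          adjacency=sp.csr_matrix(a.astype(np.int8)),
                          k_bar=a.sum() / n, rng_seed=0, p_trans=p_trans)


def test_output_strength_chain_examples():
    chain2 = np.zeros((2, 2)); chain2[0, 1] = 1
    os2 = cp.output_strength(_net_from_dense(chain2, 0.5))
    assert os2.tolist() == [0.5, 0.0]
    chain3 = np.zeros((3, 3)); chain3[0, 1] = chain3[1, 2] = 1
    os3 = cp.output_strength(_net_from_dense(chain3, 0.5))
    assert os3[0] == pytest.approx(0.75)
    assert cp.output_strength(_net_from_dense(chain3, 0.0)).sum() == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_output_strength_equals_walk_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(5, 13)
    a = (rng.random((n, n)) < 0.3).astype(int)
    np.fill_diagonal(a, 0)
    net = _net_from_dense(a, 0.3)
    got = cp.output_strength(net)
    want = brute_force_walk_strength(a, 0.3)
    np.testing.assert_allclose(got, want, rtol=1e-10)


# ---------------------------------------------------------------------------
# critical point


def test_critical_sigma_near_one_on_complete_graph():
    """Mean-field limit: single-seed cascades on a complete graph go critical
    at branching parameter 1 (survival decay exponent delta = 1)."""
    net = cp.build_lattice(side=20, spacing_um=12, gauss_amp=1.0,
                           gauss_scale_um=1e9, exp_amp=0.0, seed=0)
    # short horizon: on a finite complete graph, supercritical cascades
    # overshoot and crash once a sizeable fraction is refractory, so only
    # the early-time dynamics follow the branching process
    res = cp.find_critical_sigma(net, sigma_grid=np.arange(0.7, 1.35, 0.1),
                                 horizon=40, n_cascades=1500,
                                 refine_cascades=3000, delta=1.0, seed=4)
    assert 0.9 < res.sigma_c < 1.15
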