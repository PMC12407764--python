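"""Tests of the trial-windowed response statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

from critperturb import fixtures, response
from critperturb.recording import Recording


def _toy_recording(counts, onsets, tcs, n_tc=1):
    counts = np.asarray(counts)
    pos = np.zeros((counts.shape[0], 2))
    trials = pd.DataFrame({"tc": tcs, "onset_frame": onsets})
    return Recording(counts=counts, positions=pos,
                     tc_indices=np.arange(n_tc), trials=trials)


def test_window_arithmetic():
    """Onset at frame 100: response [100,106), base [88,94), base' [82,88)."""
    counts = np.zeros((2, 200), dtype=int)
    counts[1, 100:106] = 1    # response window only
    counts[1, 88:94] = 2      # baseline window
    counts[1, 82:88] = 3      # early baseline
    rec = _toy_recording(counts, [100], [0])
    tc = response.extract_trial_counts(rec)
    assert tc.resp[0, 1] == 6
    assert tc.base[0, 1] == 12
    assert tc.base_prime[0, 1] == 18


def test_constant_raster_gives_window_counts_of_six():
    counts = np.ones((3, 150), dtype=int)
    rec = _toy_recording(counts, [30, 80], [0, 0])
    tc = response.extract_trial_counts(rec)
    assert np.all(tc.resp == 6) and np.all(tc.base == 6)


def test_early_onset_trial_dropped():
    counts = np.ones((2, 100), dtype=int)
    rec = _toy_recording(counts, [10, 50], [0, 0])
    with pytest.warns(UserWarning):
        tc = response.extract_trial_counts(rec)
    assert tc.n_trials == 1


def test_outlier_removal_flags_extreme_trial():
    n = 200
    counts = np.zeros((2, n * 20), dtype=int)
    onsets = 20 + 20 * np.arange(n)
    rng = np.random.default_rng(0)
    counts[1] = rng.poisson(1.0, counts.shape[1])
    counts[1, onsets[5]:onsets[5] + 6] = 300  # artifact in one response window
    rec = _toy_recording(counts, onsets, np.zeros(n, dtype=int))
    tc = response.extract_trial_counts(rec)
    mask = response.remove_outlier_trials(tc)
    assert mask[5, 1]
    assert mask.mean() < 0.01


def test_outlier_removal_no_removal_when_constant():
    counts = np.ones((2, 1000), dtype=int)
    rec = _toy_recording(counts, 20 + 20 * np.arange(40),
                         np.zeros(40, dtype=int))
    tc = response.extract_trial_counts(rec)
    assert not response.remove_outlier_trials(tc).any()


def test_filter_targets_rule():
    rng = np.random.default_rng(1)
    n = 100
    counts = np.zeros((1, 20 * n + 40), dtype=int)
    onsets = 20 + 20 * np.arange(n)
    counts[0] = rng.poisson(0.5, counts.shape[1])
    # TC responds strongly in 30% of trials
    for f in onsets[: int(0.3 * n)]:
        counts[0, f:f + 6] = 10
    rec = _toy_recording(counts, onsets, np.zeros(n, dtype=int))
    tc = response.extract_trial_counts(rec)
    out = response.filter_targets(tc)
    assert bool(out.loc[0, "retained"])
    # silent TC is excluded
    counts2 = np.zeros_like(counts)
    counts2[0] = rng.poisson(0.5, counts.shape[1])
    rec2 = _toy_recording(counts2, onsets, np.zeros(n, dtype=int))
    out2 = response.filter_targets(response.extract_trial_counts(rec2))
    assert not bool(out2.loc[0, "retained"])


def test_filter_targets_binomial_tail():
    """A TC evoking suprathreshold responses in only ~15% of trials is
    excluded in nearly all seeds (binomial tail below the 20% rule)."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 200
        counts = np.ones((1, 20 * n + 40), dtype=int)  # constant baseline
        onsets = 20 + 20 * np.arange(n)
        respond = rng.random(n) < 0.15
        for f, r in zip(onsets, respond):
            if r:
                counts[0, f:f + 6] = 5
        rec = _toy_recording(counts, onsets, np.zeros(n, dtype=int))
        out = response.filter_targets(response.extract_trial_counts(rec))
        hits += not bool(out.loc[0, "retained"])
    assert hits >= 9


# ---------------------------------------------------------------------------
# classification


def test_planted_strong_responder_always_detected():
    rec, gt = fixtures.scaling_recording(seed=0, n_posr_per_tc=10,
                                         effect_range=(3.0, 4.0),
                                         trials_per_tc=80)
    counts = response.extract_trial_counts(rec)
    table = response.classify_responders(counts)
    for tc_id, cells in gt.posr.items():
        sub = table[(table["tc"] == tc_id) & (table["cell"].isin(cells))]
        assert (sub["cls"] == "PosR").all()


def test_degenerate_zero_variance_cell_is_nonr():
    counts = np.ones((2, 1000), dtype=int)
    counts[1] = 0
    rec = _toy_recording(counts, 20 + 20 * np.arange(30),
                         np.zeros(30, dtype=int))
    tc = response.extract_trial_counts(rec)
    table = response.classify_responders(tc)
    row = table[table["cell"] == 1].iloc[0]
    assert row["cls"] == "NonR" and row["degenerate"]


def test_welch_variant_close_to_z_on_nulls():
    rec, _ = fixtures.null_recording(n_cells=80, trials_per_tc=100, seed=3)
    counts = response.extract_trial_counts(rec)
    tz = response.classify_responders(counts, method="z")
    tw = response.classify_responders(counts, method="welch")
    fz = (tz["cls"] == "PosR").mean()
    fw = (tw["cls"] == "PosR").mean()
    assert abs(fz - fw) < 0.02


def test_class_exhaustiveness(scaling_counts):
    counts, table, _ = scaling_counts
    n_non_tc = counts.rec.n_cells - len(counts.rec.tc_indices)
    assert len(table) == n_non_tc * len(counts.tcs)
    assert set(table["cls"]) <= set(response.CLASSES)


# ---------------------------------------------------------------------------
# FDR


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(0)
    p = np.concatenate([np.full(10, 0.001), rng.uniform(0.1, 1, 90)])
    table = pd.DataFrame({"tc": 0, "cell": np.arange(100), "p": p,
                          "z": st.norm.isf(p), "degenerate": False})
    out = response.fdr_adjust(table, q=0.025)

    # brute-force Benjamini-Hochberg step-up
    order = np.argsort(p)
    m = len(p)
    k = max([i + 1 for i in range(m) if p[order[i]] <= 0.025 * (i + 1) / m],
            default=0)
    rejected = set(order[:k])
    got = set(np.flatnonzero(out["cls_fdr"] == "PosR"))
    assert got == rejected
    assert got >= set(range(10))  # the 10 planted discoveries survive


def test_fdr_monotone_in_q():
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 60) ** 2
    table = pd.DataFrame({"tc": 0, "cell": np.arange(60), "p": p,
                          "z": st.norm.isf(p), "degenerate": False})
    d1 = set(np.flatnonzero(
        response.fdr_adjust(table, q=0.01)["cls_fdr"] == "PosR"))
    d5 = set(np.flatnonzero(
        response.fdr_adjust(table, q=0.05)["cls_fdr"] == "PosR"))
    assert d1 <= d5


def test_fdr_no_signal_no_discoveries():
    # p = 0.5 everywhere (z = 0): neither tail yields discoveries
    table = pd.DataFrame({"tc": 0, "cell": np.arange(20),
                          "p": np.full(20, 0.5),
                          "z": np.zeros(20), "degenerate": False})
    out = response.fdr_adjust(table)
    assert (out["cls_fdr"] == "NonR").all()


# ---------------------------------------------------------------------------
# scaling fits


def test_scaling_fit_flat_and_linear_limits():
    rng = np.random.default_rng(0)
    n = 700
    counts = np.zeros((3, 20 * n + 40), dtype=int)
    onsets = 20 + 20 * np.arange(n)
    tc_counts = rng.integers(1, 8, n)
    for f, c in zip(onsets, tc_counts):
        counts[0, f] = c
        counts[1, f] = 5                      # flat responder
        counts[2, f] = 4 * c                  # linear responder
    rec = _toy_recording(counts, onsets, np.zeros(n, dtype=int))
    tcc = response.extract_trial_counts(rec)
    table = pd.DataFrame({"tc": 0, "cell": [1, 2], "cls": "PosR"})
    flat = response.scaling_fit(tcc, table[table["cell"] == 1])
    lin = response.scaling_fit(tcc, table[table["cell"] == 2])
    assert abs(flat.exponent) < 0.02
    assert lin.exponent == pytest.approx(1.0, abs=0.02)


def test_scaling_fit_undefined_without_class(scaling_counts):
    counts, table, _ = scaling_counts
    no_neg = table[table["cls"] != "NegR"]
    with pytest.raises(ValueError):
        response.scaling_fit(counts, no_neg, cls="NegR")


# ---------------------------------------------------------------------------
# Fano factors


def test_fano_hand_example():
    # counts [0,2,0,2]: mean 1, sample variance 4/3
    x = np.array([0, 2, 0, 2])
    assert response._ff(x) == pytest.approx(4 / 3)


def test_fano_poisson_fixture_near_one():
    gt = fixtures.FixtureGroundTruth(baseline_mean=1.0, fano=1.0,
                                     lag_corr=0.0, tc_count_mean=6.0)
    rec, _ = fixtures.make_recording(n_cells=80, n_tc=2, trials_per_tc=100,
                                     ground_truth=gt, seed=5)
    counts = response.extract_trial_counts(rec)
    out = response.fano(counts)
    ok = out[~out["excluded"] & ~out["is_tc"]]
    assert ok["ff_base"].mean() == pytest.approx(1.0, abs=0.08)
    assert ok["ff_stim"].mean() == pytest.approx(1.0, abs=0.08)


def test_fano_scale_invariance_property():
    """Multiplying all counts by an integer c multiplies FF by c exactly."""
    rng = np.random.default_rng(2)
    x = rng.poisson(2.0, 200)
    assert response._ff(3 * x) == pytest.approx(3 * response._ff(x))


def test_fano_mismatched_cell_excluded():
    n = 60
    counts = np.zeros((2, 30 * n + 40), dtype=int)
    onsets = 20 + 30 * np.arange(n)
    rng = np.random.default_rng(3)
    counts[1] = rng.poisson(1.0, counts.shape[1])
    for f in onsets:  # response far above any 1..9-frame baseline match
        counts[1, f:f + 9] = 20
    rec = _toy_recording(counts, onsets, np.zeros(n, dtype=int))
    out = response.fano(response.extract_trial_counts(rec))
    assert bool(out[out["cell"] == 1]["excluded"].iloc[0])


# ---------------------------------------------------------------------------
# splits, regimes, distance profile


def test_split_trials_quartiles_and_tc_rule(scaling_counts):
    counts, _, _ = scaling_counts
    masks = response.split_trials(counts, "baseline")
    n = counts.n_trials
    assert not (masks["low"] & masks["high"]).any()
    assert 0.1 < masks["low"].mean() < 0.4
    assert 0.1 < masks["high"].mean() < 0.4
    tc_masks = response.split_trials(counts, "tc_count")
    assert not (tc_masks["low"] & tc_masks["high"]).any()
    timing = response.split_trials(counts, "timing")
    for info in timing.values():
        early, late = info["early"], info["late"]
        assert early[1] == late[0]  # adjacent, non-overlapping
        assert early[1] - early[0] == late[1] - late[0] == 6


def test_baseline_regime_slopes():
    rng = np.random.default_rng(4)
    n = 300
    n_cells = 120
    counts = np.zeros((n_cells, 20 * n + 40), dtype=int)
    onsets = 20 + 20 * np.arange(n)
    rates = np.linspace(0.02, 1.0, n_cells)
    for i, mu in enumerate(rates):
        counts[i] = rng.poisson(mu, counts.shape[1])
    rec = _toy_recording(counts, onsets, np.zeros(n, dtype=int))
    tcc = response.extract_trial_counts(rec)
    out = response.baseline_regime_scaling(tcc, theta_grid=(0.3,))
    # stationary counts: response equals baseline on average -> slope 1
    assert out.slope_high[0.3] == pytest.approx(1.0, abs=0.1)


def test_responder_distance_profile_step():
    rec, gt = fixtures.decoding_recording(seed=1, within_radius_um=50.0)
    table = fixtures.ground_truth_table(rec, gt)
    prof = response.responder_distance_profile(table, rec,
                                               radii=[0, 50, 150, 400])
    assert prof["frac_posr"].iloc[0] > 3 * max(prof["frac_posr"].iloc[2], 0.01)


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=25, deadline=None)
@given(hst.integers(min_value=0, max_value=2**31 - 1))
def test_type_one_rate_alpha_sweep_property(seed):
    """Classifier alpha and empirical PosR rate agree on tiny nulls."""
    rng = np.random.default_rng(seed)
    n, cells = 60, 15
    counts = rng.poisson(5.0, (cells, 20 * n + 40))
    rec = _toy_recording(counts, 20 + 20 * np.arange(n),
                         np.zeros(n, dtype=int))
    tcc = response.extract_trial_counts(rec)
    table = response.classify_responders(tcc, alpha=0.2)
    frac = (table["cls"] == "PosR").mean()
    assert 0.0 <= frac <= 0.6  # loose per-example bound; mean checked below
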