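"""Synthetic recordings with planted ground truth.

Generates Recording objects that emulate deconvolved two-photon spike-count
rasters — sparse, overdispersed baseline counts with short-range temporal
autocorrelation — plus stimulation trials with planted positive/negative
responders whose mean response follows a power law in the target-cell spike
count.  Every analysis stage can thereby be tested for parameter recovery
independently of the lattice simulator.  Also provides simple
branching-process population traces for the avalanche stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import Recording


@dataclass
class FixtureGroundTruth:
    """Planted structure of a synthetic recording.

    Baseline counts are negative binomial with mean ``baseline_mean`` per
    frame and variance ``fano * mean``, modulated by a latent per-cell AR(1)
    rate process whose amplitude is solved so that spike counts in adjacent
    6-frame windows correlate at ``lag_corr``.  During a trial of target tc
    with spike count c, each planted positive responder's response window is
    driven at mean ``effect * c**h_true`` (replacing ongoing activity by
    default; see make_recording); negative responders are decremented by the
    same amount, floored at zero.
    """

    posr: dict = field(default_factory=dict)        # tc -> cell id array
    negr: dict = field(default_factory=dict)
    effects_pos: dict = field(default_factory=dict)  # tc -> per-cell effect
    effects_neg: dict = field(default_factory=dict)
    h_true: float = 0.3
    baseline_mean: float = 0.1    # spikes per frame per cell
    fano: float = 2.0             # variance/mean of baseline counts
    ar_coef: float = 0.9          # per-frame AR(1) coefficient of the latent rate
    lag_corr: float = 0.2         # adjacent 6-frame-window count correlation
    tc_count_mean: float = 2.5    # mean TC spikes per 6-frame response window

    def __post_init__(self):
        if self.h_true < 0:
            raise ValueError("h_true must be positive")
        if self.fano < 1:
            raise ValueError("dispersion below Poisson is not supported")
        for tc in self.posr:
            overlap = np.intersect1d(self.posr[tc], self.negr.get(tc, []))
            if overlap.size:
                raise ValueError("posr and negr sets overlap")


def _implied_window_corr(sigma_g: float, gt: FixtureGroundTruth,
                         window: int) -> float:
    """Correlation of adjacent window sums under the log-normal AR modulator.

    The rate is mu * exp(sigma_g * x - sigma_g^2/2) with x a unit-variance
    AR(1); count covariances follow from the exact lognormal autocovariance
    mu^2 * (exp(sigma_g^2 * phi^lag) - 1).
    """
    phi = gt.ar_coef
    mu = gt.baseline_mean
    i = np.arange(window)
    lag11 = np.abs(i[:, None] - i[None, :])
    lag12 = np.abs(i[:, None] + window - i[None, :])
    c11 = (np.exp(sigma_g**2 * phi**lag11) - 1).sum()
    c12 = (np.exp(sigma_g**2 * phi**lag12) - 1).sum()
    return mu * c12 / (window * gt.fano + mu * c11)


def _modulator_sigma(gt: FixtureGroundTruth, window: int = 6) -> float:
    """Solve the log-normal modulator scale for the target lag correlation."""
    from scipy.optimize import brentq
    r = gt.lag_corr
    if r <= 0:
        return 0.0
    # r(sigma) rises, peaks, then falls (extreme bursts decorrelate windows):
    # solve on the rising branch up to the peak
    grid = np.linspace(1e-3, 4.0, 200)
    vals = np.array([_implied_window_corr(s, gt, window) for s in grid])
    peak = int(np.argmax(vals))
    if vals[peak] < r:
        raise ValueError("requested lag correlation is unreachable with this "
                         "AR coefficient / rate")
    return float(brentq(lambda s: _implied_window_corr(s, gt, window) - r,
                        1e-6, grid[peak]))


def _nb_counts(rng, mean, fano):
    """Negative-binomial counts with given mean and Fano factor (Poisson at 1)."""
    mean = np.asarray(mean, dtype=float)
    if fano <= 1.0:
        return rng.poisson(mean)
    p = 1.0 / fano
    r = mean / (fano - 1.0)
    # gamma-Poisson mixture handles mean arrays with zero entries gracefully
    lam = rng.gamma(np.where(r > 0, r, 1.0), (1.0 - p) / p * np.ones_like(mean))
    lam = np.where(r > 0, lam, 0.0)
    return rng.poisson(lam)


def trial_schedule(n_tc: int, trials_per_tc: int, first_onset: int = 20,
                   period: int = 91, seed: int = 0) -> pd.DataFrame:
    """Round-interleaved trial onsets (frames), one stimulation per period."""
    rng = np.random.default_rng(seed)
    order = np.concatenate([rng.permutation(n_tc) for _ in range(trials_per_tc)])
    onsets = first_onset + period * np.arange(len(order))
    return pd.DataFrame({"tc": order, "onset_frame": onsets})


def make_recording(n_cells: int = 200, n_tc: int = 10,
                   trials_per_tc: int = 100,
                   ground_truth: FixtureGroundTruth | None = None,
                   window_frames: int = 6, period_frames: int = 91,
                   first_onset: int = 20, fov_um: float = 456.0,
                   posr_mode: str = "override", seed: int = 0):
    """Synthesise a Recording plus its ground truth.

    ``posr_mode='override'`` (default) makes the planted positive response
    replace ongoing activity in the window (window mean = effect * c**h);
    ``'increment'`` adds it on top of baseline instead.

    TC cells are rows 0..n_tc-1 (their ids are shuffled into random
    positions spatially but kept as the first rows for clarity of the planted
    structure).  Returns (Recording, FixtureGroundTruth).
    """
    gt = ground_truth if ground_truth is not None else FixtureGroundTruth()
    if first_onset < 18:
        raise ValueError("need an 18-frame pre-onset margin")
    rng = np.random.default_rng(seed)

    trials = trial_schedule(n_tc, trials_per_tc, first_onset, period_frames,
                            seed=seed)
    n_frames = int(trials["onset_frame"].iloc[-1] + window_frames +
                   period_frames) if len(trials) else 2000

    # baseline: latent log-normal AR(1) rate modulator per cell
    sg = _modulator_sigma(gt, window_frames)
    mean = np.full((n_cells, n_frames), gt.baseline_mean)
    if sg > 0:
        phi = gt.ar_coef
        x = np.empty((n_cells, n_frames))
        x[:, 0] = rng.standard_normal(n_cells)
        innov = rng.standard_normal((n_cells, n_frames)) * np.sqrt(1 - phi**2)
        for t in range(1, n_frames):
            x[:, t] = phi * x[:, t - 1] + innov[:, t]
        mean = mean * np.exp(sg * x - 0.5 * sg**2)
    counts = _nb_counts(rng, mean, gt.fano).astype(np.int64)

    # stimulation: inject TC counts and planted responder effects
    tc_ids = np.arange(n_tc)
    for _, row in trials.iterrows():
        tc, f0 = int(row["tc"]), int(row["onset_frame"])
        win = slice(f0, f0 + window_frames)
        c = 1 + rng.poisson(max(gt.tc_count_mean - 1.0, 0.0))
        counts[tc, win] = rng.multinomial(c, np.full(window_frames,
                                                     1 / window_frames))
        for cells, effects, sign in ((gt.posr.get(tc), gt.effects_pos.get(tc), 1),
                                     (gt.negr.get(tc), gt.effects_neg.get(tc), -1)):
            if cells is None or len(cells) == 0:
                continue
            lam = np.asarray(effects, dtype=float) * c ** gt.h_true
            delta = rng.poisson(lam)
            for cell, d in zip(cells, delta):
                spread = rng.multinomial(d, np.full(window_frames,
                                                    1 / window_frames))
                if sign > 0:
                    if posr_mode == "override":
                        # stimulus-driven spiking replaces ongoing activity,
                        # so the total window mean is effect * c**h exactly
                        counts[cell, win] = spread
                    else:
                        counts[cell, win] += spread
                else:
                    counts[cell, win] = np.maximum(counts[cell, win] - spread, 0)

    positions = rng.uniform(0, fov_um, size=(n_cells, 2))
    rec = Recording(counts=counts.astype(np.uint16), positions=positions,
                    tc_indices=tc_ids, trials=trials,
                    meta={"source": "fixture", "seed": seed,
                          "h_true": gt.h_true})
    return rec, gt


def ground_truth_table(rec: Recording, gt: FixtureGroundTruth) -> pd.DataFrame:
    """Responder table built from the planted ground truth (oracle classes).

    Same layout as the classifier's output so downstream operations (scaling
    fits, drop-probability curves) can be evaluated against the truth.
    """
    rows = []
    for tc in rec.tc_indices:
        pos = set(map(int, gt.posr.get(int(tc), [])))
        neg = set(map(int, gt.negr.get(int(tc), [])))
        for cell in rec.non_tc_indices:
            cls = "PosR" if cell in pos else "NegR" if cell in neg else "NonR"
            rows.append({"tc": int(tc), "cell": int(cell), "cls": cls})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets


def null_recording(n_cells: int = 200, n_tc: int = 10,
                   trials_per_tc: int = 150, baseline_mean: float = 2.0,
                   fano: float = 1.0, lag_corr: float = 0.0,
                   seed: int = 0):
    """High-rate null fixture: pseudo-TC trial onsets with no planted effect.

    The default high Poisson baseline makes the normal approximation of the
    responder test accurate, so the empirical type-I rate can be read off
    directly.
    """
    gt = FixtureGroundTruth(baseline_mean=baseline_mean, fano=fano,
                            lag_corr=lag_corr, tc_count_mean=baseline_mean * 6)
    return make_recording(n_cells=n_cells, n_tc=n_tc,
                          trials_per_tc=trials_per_tc, ground_truth=gt,
                          seed=seed)


def scaling_recording(n_cells: int = 200, n_tc: int = 10,
                      trials_per_tc: int = 150, h_true: float = 0.3,
                      n_posr_per_tc: int = 30, effect_range=(1.0, 2.0),
                      n_negr_per_tc: int = 0, baseline_mean: float = 0.1,
                      fano: float = 2.0, lag_corr: float = 0.2,
                      seed: int = 0):
    """Fixture with planted power-law responders for scaling-fit recovery."""
    rng = np.random.default_rng(seed + 77)
    non_tc = np.arange(n_tc, n_cells)
    posr, negr, epos, eneg = {}, {}, {}, {}
    for tc in range(n_tc):
        chosen = rng.choice(non_tc, size=n_posr_per_tc + n_negr_per_tc,
                            replace=False)
        posr[tc] = np.sort(chosen[:n_posr_per_tc])
        epos[tc] = rng.uniform(*effect_range, size=n_posr_per_tc)
        if n_negr_per_tc:
            negr[tc] = np.sort(chosen[n_posr_per_tc:])
            eneg[tc] = rng.uniform(*effect_range, size=n_negr_per_tc)
    gt = FixtureGroundTruth(posr=posr, negr=negr, effects_pos=epos,
                            effects_neg=eneg, h_true=h_true,
                            baseline_mean=baseline_mean, fano=fano,
                            lag_corr=lag_corr)
    return make_recording(n_cells=n_cells, n_tc=n_tc,
                          trials_per_tc=trials_per_tc, ground_truth=gt,
                          seed=seed)


def decoding_recording(n_cells: int = 120, n_tc: int = 5,
                       trials_per_tc: int = 60, n_informative: int = 6,
                       effect: float = 3.0, within_radius_um: float | None = 50.0,
                       baseline_mean: float = 0.1, seed: int = 0):
    """Fixture where each TC drives its own small signature cell set.

    Informative cells are optionally placed within ``within_radius_um`` of
    their TC so spatial exclusion analyses have a known critical radius.
    """
    rng = np.random.default_rng(seed + 177)
    non_tc = rng.permutation(np.arange(n_tc, n_cells))
    posr, epos = {}, {}
    for tc in range(n_tc):
        cells = np.sort(non_tc[tc * n_informative:(tc + 1) * n_informative])
        posr[tc] = cells
        epos[tc] = np.full(n_informative, effect)
    gt = FixtureGroundTruth(posr=posr, effects_pos=epos, h_true=0.3,
                            baseline_mean=baseline_mean)
    rec, gt = make_recording(n_cells=n_cells, n_tc=n_tc,
                             trials_per_tc=trials_per_tc, ground_truth=gt,
                             seed=seed)
    if within_radius_um is not None:
        pos = rec.positions
        for tc in range(n_tc):
            for cell in posr[tc]:
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(5.0, within_radius_um)
                pos[cell] = pos[tc] + rad * np.array([np.cos(ang), np.sin(ang)])
    return rec, gt


# ---------------------------------------------------------------------------
# branching-process traces


def make_branching_trace(n_steps: int, offspring_mean: float,
                         immigration: float, seed: int = 0) -> np.ndarray:
    """Galton-Watson population counts with Poisson offspring and immigration.

    At offspring_mean = 1 cluster sizes are heavy-tailed; well below 1 they
    decay essentially exponentially.
    """
    if offspring_mean < 0:
        raise ValueError("offspring_mean must be >= 0")
    rng = np.random.default_rng(seed)
    z = np.empty(n_steps, dtype=np.int64)
    cur = 0
    for t in range(n_steps):
        cur = rng.poisson(offspring_mean * cur) + rng.poisson(immigration)
        z[t] = cur
    return z


def branching_cluster_sizes(n_clusters: int, offspring_mean: float,
                            seed: int = 0, max_size: int = 10**6) -> np.ndarray:
    """Total progeny (including the founder) of independent single-immigrant
    cascades; E[size] = 1/(1-m) for subcritical offspring mean m."""
    rng = np.random.default_rng(seed)
    sizes = np.empty(n_clusters, dtype=np.int64)
    for i in range(n_clusters):
        total, gen = 1, 1
        while gen > 0 and total < max_size:
            gen = rng.poisson(offspring_mean * gen)
            total += gen
        sizes[i] = total
    return sizes
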