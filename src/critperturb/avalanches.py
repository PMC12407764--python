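"""Neuronal-avalanche statistics on population spike-count traces.

Pipeline: soft-threshold the population trace (subtract a threshold, clip at
zero), choose the threshold from the log-normal shape of the epoch-count
curve N(theta), apply temporal coarse-graining (an ensemble of k phase-offset
series of k-frame sums), extract avalanches as maximal positive runs bounded
by zeros, pool events across phases, and fit the mean-size-versus-duration
curve with a double power law whose initial slope distinguishes parabolic
(size ~ duration^2) from linear avalanche growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def soft_threshold(trace, theta: float) -> np.ndarray:
    """p_theta(t) = p(t) - theta where p(t) > theta, else 0."""
    trace = np.asarray(trace, dtype=float)
    return np.where(trace > theta, trace - theta, 0.0)


def coarse_grain(trace, k: int) -> list:
    """Ensemble of k phase-offset coarse-grained series.

    Phase j sums the k frames starting at k*tau + j; trailing incomplete
    windows are dropped.  k = 1 returns the original series.
    """
    trace = np.asarray(trace, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for j in range(k):
        x = trace[j:]
        n = len(x) // k
        out.append(x[:n * k].reshape(n, k).sum(axis=1))
    return out


def extract_avalanches(series) -> pd.DataFrame:
    """Maximal positive runs bounded by zeros: size = sum, duration = length.

    Runs touching the series boundaries without a bounding zero are
    discarded (the definition requires a zero on both sides).
    """
    x = np.asarray(series, dtype=float)
    pos = x > 0
    # run boundaries
    d = np.diff(pos.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1  # exclusive
    if pos.size and pos[0]:
        # leading run lacks a left bounding zero -> drop its end marker
        if len(ends) and (not len(starts) or ends[0] < starts[0]):
            ends = ends[1:]
    if len(starts) > len(ends):  # trailing run lacks a right bounding zero
        starts = starts[:len(ends)]
    sizes = [x[s:e].sum() for s, e in zip(starts, ends)]
    durs = [e - s for s, e in zip(starts, ends)]
    return pd.DataFrame({"size": sizes, "duration": durs})


def count_epochs(trace, theta: float, k: int) -> int:
    """Number of pooled avalanches after soft-thresholding and coarse-graining."""
    thr = soft_threshold(trace, theta)
    return int(sum(len(extract_avalanches(s)) for s in coarse_grain(thr, k)))


@dataclass
class ThresholdFit:
    theta_grid: np.ndarray
    n_epochs: np.ndarray
    mu: float                 # log-location of the fitted log-normal shape
    sigma_ln: float
    theta_star: float         # selected threshold (exp(mu) by default)
    k: int
    fit_ok: bool


def select_threshold(trace, k: int = 1, theta_grid=None,
                     use_exp_mu: bool = True) -> ThresholdFit:
    """Data-driven threshold: fit a log-normal shape to N(theta).

    The grid spans theta_1 (removes no activity) to theta_2 (removes all
    activity); N(theta) counts epochs after coarse-graining at k.  The
    threshold is the fitted log-location mapped back to the count axis
    (theta* = exp(mu); ``use_exp_mu=False`` selects raw mu instead).  If the
    fit fails the argmax of N(theta) is used and flagged.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.max() <= 0:
        raise ValueError("trace has no activity")
    if theta_grid is None:
        theta_grid = np.arange(0.0, trace.max() + 1.0)
    theta_grid = np.asarray(theta_grid, dtype=float)
    n = np.array([count_epochs(trace, th, k) for th in theta_grid])

    def lognorm_shape(th, amp, mu, s):
        th = np.asarray(th, dtype=float)
        out = np.zeros_like(th)
        ok = th > 0
        out[ok] = amp * np.exp(-(np.log(th[ok]) - mu)**2 / (2 * s**2))
        return out

    pos = theta_grid > 0
    fit_ok = True
    try:
        mode_guess = max(theta_grid[np.argmax(n)], 1.0)
        popt, _ = curve_fit(lognorm_shape, theta_grid[pos], n[pos],
                            p0=[n.max(), np.log(mode_guess), 1.0],
                            maxfev=10000)
        amp, mu, s = popt
        s = abs(s)
        if not np.isfinite(mu):
            raise RuntimeError
    except Exception:
        fit_ok = False
        mu = np.log(max(theta_grid[np.argmax(n)], 1.0))
        s = np.nan
    theta_star = float(np.exp(mu)) if use_exp_mu else float(mu)
    return ThresholdFit(theta_grid, n, float(mu), float(s), theta_star, k,
                        fit_ok)


def build_catalog(trace, ks=(1, 2, 4, 8), theta="auto") -> pd.DataFrame:
    """Avalanche catalog across coarse-graining factors.

    For each k the threshold is selected on that k (or a fixed number may be
    supplied); events from all phases are pooled.  Columns: k, phase, size,
    duration, theta.
    """
    frames = []
    for k in ks:
        if theta == "auto":
            th = select_threshold(trace, k=k).theta_star
        else:
            th = float(theta)
        thr = soft_threshold(trace, th)
        for j, series in enumerate(coarse_grain(thr, k)):
            ev = extract_avalanches(series)
            ev["k"] = k
            ev["phase"] = j
            ev["theta"] = th
            frames.append(ev)
    return pd.concat(frames, ignore_index=True)


def mean_size_vs_duration(catalog: pd.DataFrame) -> pd.DataFrame:
    """Mean avalanche size per exact integer duration, with occupancy."""
    if not len(catalog):
        raise ValueError("empty avalanche catalog")
    g = catalog.groupby("duration")["size"]
    out = g.mean().rename("mean_size").reset_index()
    out["n"] = g.size().to_numpy()
    return out


@dataclass
class ScalingCurveFit:
    """Double power law S(d) = C d^chi_sh [1 + (d/Phi)^g]^((chi_lg-chi_sh)/g)."""

    C: float
    chi_sh: float
    chi_lg: float
    phi: float
    gamma_sharp: float
    residual: float
    converged: bool

    def predict(self, d):
        d = np.asarray(d, dtype=float)
        g = self.gamma_sharp
        return (self.C * d**self.chi_sh *
                (1 + (d / self.phi)**g)**((self.chi_lg - self.chi_sh) / g))


def fit_scaling_curve(curve: pd.DataFrame, gamma_sharp: float = 4.0,
                      weighted: bool = False) -> ScalingCurveFit:
    """Fit the mean-size-vs-duration curve in log-log space.

    The transition sharpness is fixed (gamma_sharp = 4); C, the initial
    slope chi_sh, the asymptotic slope chi_lg and the crossover Phi are free.
    Multi-start nonlinear least squares; the best-of-starts fit is returned
    with its residual, flagged when no start converged.
    """
    d = curve["duration"].to_numpy(dtype=float)
    s = curve["mean_size"].to_numpy(dtype=float)
    ok = (d > 0) & (s > 0)
    d, s = d[ok], s[ok]
    if len(np.unique(d)) < 6:
        raise ValueError("need at least 6 distinct durations")
    ld, ls = np.log(d), np.log(s)
    w = np.sqrt(curve["n"].to_numpy(dtype=float)[ok]) if weighted else None

    def model(ld_, logC, chi_sh, chi_lg, log_phi):
        dd = np.exp(ld_)
        g = gamma_sharp
        return (logC + chi_sh * ld_ +
                (chi_lg - chi_sh) / g * np.log1p((dd / np.exp(log_phi))**g))

    best = None
    starts = [(0.0, c1, c2, np.log(p))
              for c1 in (1.0, 2.0, 3.0)
              for c2 in (0.5, 1.0, 1.5)
              for p in np.quantile(d, (0.3, 0.6, 0.9))]
    import warnings as _warnings
    from scipy.optimize import OptimizeWarning
    for p0 in starts:
        try:
            with _warnings.catch_warnings():
                # singular covariances are expected for bad starts
                _warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(model, ld, ls, p0=p0, maxfev=5000,
                                    sigma=1.0 / w if w is not None else None)
            resid = float(np.sum((model(ld, *popt) - ls)**2))
            if best is None or resid < best[1]:
                best = (popt, resid)
        except Exception:
            continue
    if best is None:
        return ScalingCurveFit(np.nan, np.nan, np.nan, np.nan, gamma_sharp,
                               np.inf, False)
    (logC, chi_sh, chi_lg, log_phi), resid = best
    return ScalingCurveFit(float(np.exp(logC)), float(chi_sh), float(chi_lg),
                           float(np.exp(log_phi)), gamma_sharp, resid, True)


def parabolic_summary(catalog: pd.DataFrame, d_max_frames: float,
                      frame_ms: float = 22.0) -> dict:
    """Fractions of avalanches and of spikes in avalanches shorter than a
    duration cutoff (in coarse bins' original-frame units)."""
    if not len(catalog):
        raise ValueError("empty avalanche catalog")
    dur_frames = catalog["duration"] * catalog["k"]
    short = dur_frames < d_max_frames
    event_frac = float(short.mean())
    total = catalog["size"].sum()
    spike_frac = float(catalog.loc[short, "size"].sum() / total) if total else 0.0
    return {"event_frac": event_frac, "spike_frac": spike_frac,
            "d_max_frames": d_max_frames, "d_max_s": d_max_frames * frame_ms / 1000}
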