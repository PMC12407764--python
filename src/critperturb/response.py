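"""Trial-windowed perturbation-response statistics.

Implements the response pipeline applied to Recordings: windowed trial
counts, outlier-trial removal, target filtering, responder classification
(PosR / NegR / NonR) with optional FDR correction, response-scaling fits,
auto/cross-correlation analysis, mean-matched Fano factors, trial splits,
baseline-regime scaling and responder distance profiles.

Window conventions (frames are 0-based, windows half-open): for a trial
onset at frame f with the default 6-frame (132 ms) windows, the response
window is [f, f+6), the baseline window [f-12, f-6) (starting ~264 ms before
onset) and the early-baseline window [f-18, f-12), so consecutive windows
are separated by one 132-ms window length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .recording import Recording

CLASSES = ("PosR", "NegR", "NonR")


def window_counts(rec: Recording, onset_frames, offset: int,
                  length: int) -> np.ndarray:
    """(n_trials, n_cells) spike counts in [onset+offset, onset+offset+length)."""
    onsets = np.asarray(onset_frames, dtype=int)
    starts = onsets + offset
    if np.any(starts < 0) or np.any(starts + length > rec.n_frames):
        raise ValueError("window extends outside the recording")
    idx = starts[:, None] + np.arange(length)[None, :]
    return rec.counts[:, idx].sum(axis=2).T.astype(np.int64)


@dataclass
class TrialCounts:
    """Per-(trial, cell) spike counts in the three analysis windows."""

    rec: Recording
    window_frames: int
    resp: np.ndarray          # (n_trials, n_cells)
    base: np.ndarray
    base_prime: np.ndarray
    trial_tc: np.ndarray      # cell index of the stimulated TC per trial
    onset_frames: np.ndarray
    removed: np.ndarray = None  # (n_trials, n_cells) outlier mask

    def __post_init__(self):
        if self.removed is None:
            self.removed = np.zeros(self.resp.shape, dtype=bool)

    @property
    def n_trials(self) -> int:
        return len(self.trial_tc)

    @property
    def tcs(self) -> np.ndarray:
        return np.unique(self.trial_tc)

    def trials_of(self, tc) -> np.ndarray:
        return np.flatnonzero(self.trial_tc == tc)


def extract_trial_counts(rec: Recording, window_frames: int = 6) -> TrialCounts:
    """Windowed trial counts; trials too close to the recording edge are
    dropped with a warning (18-frame pre-onset margin required)."""
    if rec.trials is None or not len(rec.trials):
        raise ValueError("recording has no stimulation trials")
    w = window_frames
    onsets = rec.trials["onset_frame"].to_numpy(dtype=int)
    tcs = rec.trials["tc"].to_numpy(dtype=int)  # cell row of the stimulated TC
    ok = (onsets >= 3 * w) & (onsets + w <= rec.n_frames)
    if not ok.all():
        warnings.warn(f"dropped {(~ok).sum()} trial(s) violating window margins")
    onsets, tcs = onsets[ok], tcs[ok]
    return TrialCounts(
        rec=rec, window_frames=w,
        resp=window_counts(rec, onsets, 0, w),
        base=window_counts(rec, onsets, -2 * w, w),
        base_prime=window_counts(rec, onsets, -3 * w, w),
        trial_tc=tcs, onset_frames=onsets)


def remove_outlier_trials(counts: TrialCounts, n_sd: float = 10.0) -> np.ndarray:
    """Flag (trial, cell) entries whose count exceeds mean + n_sd * SD.

    Statistics are computed per cell within each TC's trial group and per
    window; a zero SD removes nothing.  The mask is stored on ``counts`` and
    returned; the flagged fraction is reported via the mask itself.
    """
    mask = np.zeros(counts.resp.shape, dtype=bool)
    for tc in counts.tcs:
        tr = counts.trials_of(tc)
        if len(tr) < 2:
            continue
        for arr in (counts.resp, counts.base, counts.base_prime):
            x = arr[tr]
            mu = x.mean(axis=0)
            sd = x.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore"):
                bad = (sd > 0) & (x > mu + n_sd * sd)
            mask[tr] |= bad
    counts.removed = mask
    return mask


def filter_targets(counts: TrialCounts, min_responding_frac: float = 0.2,
                   percentile: float = 91.0,
                   min_trials: int = 10) -> pd.DataFrame:
    """Retain TCs for which at least ``min_responding_frac`` of trials evoke a
    response count above the ``percentile``-th percentile of the TC's own
    baseline counts.  TCs with fewer than ``min_trials`` trials are flagged
    unreliable."""
    rows = []
    for tc in counts.tcs:
        tr = counts.trials_of(tc)
        thr = np.percentile(counts.base[tr, tc], percentile)
        frac = float(np.mean(counts.resp[tr, tc] > thr))
        rows.append({"tc": tc, "n_trials": len(tr),
                     "responding_frac": frac,
                     "retained": frac >= min_responding_frac,
                     "unreliable": len(tr) < min_trials})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# responder classification


def classify_responders(counts: TrialCounts, alpha: float = 0.025,
                        method: str = "z") -> pd.DataFrame:
    """Classify each (TC, non-target cell) pair as PosR / NegR / NonR.

    Default ``method='z'``: z = (mean_resp - mean_base) / (SD_base * sqrt(2/n)),
    a z-test of the mean response against the baseline distribution with the
    two-sample standard error under the baseline-variance null (both window
    means are estimated from the same n trials, so the null variance of their
    difference is 2 SD_base^2 / n); PosR when z exceeds the upper alpha
    quantile of the standard normal, NegR below the lower alpha quantile.
    ``method='welch'`` uses a one-tailed Welch t statistic with
    Welch-Satterthwaite degrees of freedom instead.
    Cells with zero baseline SD are classified NonR and flagged degenerate.
    The one-sided upper-tail p-value is reported ("p"); the table carries the
    alpha and method used in ``attrs``.
    """
    rows = []
    non_tc = np.setdiff1d(np.arange(counts.rec.n_cells), counts.rec.tc_indices)
    for tc in counts.tcs:
        tr = counts.trials_of(tc)
        if len(tr) < 2:
            raise ValueError("need at least 2 trials per TC")
        for cell in non_tc:
            keep = tr[~counts.removed[tr, cell]]
            n = len(keep)
            if n < 2:
                continue
            b = counts.base[keep, cell]
            r = counts.resp[keep, cell]
            mb, mr = b.mean(), r.mean()
            sb = b.std(ddof=1)
            degenerate = sb == 0
            if degenerate:
                z, p = 0.0, 0.5
            elif method == "z":
                z = (mr - mb) / (sb * np.sqrt(2.0 / n))
                p = st.norm.sf(z)
            elif method == "welch":
                sr = r.std(ddof=1)
                se2 = (sr**2 + sb**2) / n
                if se2 == 0:
                    z, p, degenerate = 0.0, 0.5, True
                else:
                    z = (mr - mb) / np.sqrt(se2)
                    df = se2**2 / ((sr**2 / n)**2 / (n - 1) +
                                   (sb**2 / n)**2 / (n - 1))
                    p = st.t.sf(z, df)
            else:
                raise ValueError(f"unknown method {method!r}")
            if degenerate:
                cls = "NonR"
            elif z > st.norm.ppf(1 - alpha):
                cls = "PosR"
            elif z < st.norm.ppf(alpha):
                cls = "NegR"
            else:
                cls = "NonR"
            rows.append({"tc": tc, "cell": cell, "z": z, "p": p, "cls": cls,
                         "base_mean": mb, "base_sd": sb, "resp_mean": mr,
                         "n_trials": n, "degenerate": degenerate})
    table = pd.DataFrame(rows)
    table.attrs["alpha"] = alpha
    table.attrs["method"] = method
    return table


def _storey_qvalues(p, lam: float = 0.5):
    p = np.asarray(p, dtype=float)
    m = len(p)
    pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam)) if m else 1.0
    pi0 = max(pi0, 1.0 / m) if m else 1.0
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        prev = min(prev, pi0 * p[i] * m / (rank + 1))
        q[i] = prev
    return q


def fdr_adjust(table: pd.DataFrame, q: float = 0.025,
               method: str = "bh") -> pd.DataFrame:
    """Add q-values and re-derive classes at the FDR threshold.

    Positive and negative tails are adjusted separately (q_pos from the
    upper-tail p-values, q_neg from the lower tail); ``method`` is
    Benjamini-Hochberg ('bh', default) or Storey's pi0-adjusted q-values
    ('storey').  Discoveries at a smaller q are a subset of those at a
    larger q.
    """
    out = table.copy()
    p_pos = out["p"].to_numpy()
    p_neg = 1.0 - p_pos
    if method == "bh":
        q_pos = multipletests(p_pos, method="fdr_bh")[1]
        q_neg = multipletests(p_neg, method="fdr_bh")[1]
    elif method == "storey":
        q_pos = _storey_qvalues(p_pos)
        q_neg = _storey_qvalues(p_neg)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    out["q_pos"] = q_pos
    out["q_neg"] = q_neg
    cls = np.where(q_pos <= q, "PosR", np.where(q_neg <= q, "NegR", "NonR"))
    cls[out["degenerate"].to_numpy()] = "NonR"
    out["cls_fdr"] = cls
    out.attrs.update(table.attrs)
    out.attrs["fdr_q"] = q
    out.attrs["fdr_method"] = method
    return out


def responders_vs_alpha(counts: TrialCounts, alpha_grid,
                        method: str = "z", fdr: bool = True) -> pd.DataFrame:
    """Fraction of (TC, cell) pairs per class as a function of alpha."""
    rows = []
    for alpha in np.asarray(alpha_grid, dtype=float):
        table = classify_responders(counts, alpha=alpha, method=method)
        frac = table["cls"].value_counts(normalize=True)
        row = {"alpha": alpha}
        row.update({c: float(frac.get(c, 0.0)) for c in CLASSES})
        if fdr:
            t2 = fdr_adjust(table, q=alpha)
            frac2 = t2["cls_fdr"].value_counts(normalize=True)
            row.update({f"{c}_fdr": float(frac2.get(c, 0.0)) for c in CLASSES})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scaling fits


@dataclass
class ScalingFit:
    """Power-law fit of class response vs TC spike count (log-log space)."""

    exponent: float
    intercept: float
    ci95: tuple
    r2: float
    mode: str
    phase: str
    bins: np.ndarray          # TC-count bin values used
    bin_means: np.ndarray     # mean class response per bin
    bin_n: np.ndarray         # trials per bin

    @property
    def h(self):
        return self.exponent


def scaling_xy(counts: TrialCounts, table: pd.DataFrame,
               mode: str = "population", phase: str = "stim",
               cls: str = "PosR"):
    """Per-trial (TC count, class response) pairs feeding the scaling fit.

    Outlier-flagged (trial, cell) entries are excluded from the class sum
    (the summed response is rescaled by the surviving cell fraction).
    """
    x_arr = counts.resp if phase == "stim" else counts.base
    cell_sets = {tc: table.loc[(table["tc"] == tc) & (table["cls"] == cls),
                               "cell"].to_numpy()
                 for tc in counts.tcs}
    if all(len(v) == 0 for v in cell_sets.values()):
        raise ValueError(f"no cells of class {cls!r}; fit undefined")
    xs, ys = [], []
    for tc in counts.tcs:
        cells = cell_sets[tc]
        if len(cells) == 0:
            continue
        tr = counts.trials_of(tc)
        tc_count = x_arr[tr, tc]
        vals = x_arr[tr][:, cells].astype(float)
        keep = ~counts.removed[tr][:, cells]
        n_keep = keep.sum(axis=1)
        good = n_keep > 0
        y = np.where(good,
                     (vals * keep).sum(axis=1) * len(cells)
                     / np.maximum(n_keep, 1), np.nan)
        if mode == "per_neuron":
            y = y / len(cells)
        elif mode != "population":
            raise ValueError(f"unknown mode {mode!r}")
        xs.append(tc_count[good])
        ys.append(y[good])
    return np.concatenate(xs), np.concatenate(ys)


def scaling_fit(counts: TrialCounts, table: pd.DataFrame,
                mode: str = "population", phase: str = "stim",
                cls: str = "PosR", bins=None) -> ScalingFit:
    """Fit response = C * (TC count)^h over integer TC-count bins (1..7).

    Trials are binned by the TC's own spike count in the relevant window;
    the response is the summed (``mode='population'``) or per-cell mean
    (``mode='per_neuron'``) spike count of the chosen responder class in the
    same window.  h is the least-squares slope in log-log space with a 95%
    CI from the regression.
    """
    xs, ys = scaling_xy(counts, table, mode=mode, phase=phase, cls=cls)
    return fit_scaling_xy(xs, ys, mode=mode, phase=phase, bins=bins)


def fit_scaling_xy(xs, ys, mode: str = "population", phase: str = "stim",
                   bins=None) -> ScalingFit:
    """Bin pooled (TC count, response) pairs and fit the log-log slope."""
    if bins is None:
        bins = np.arange(1, 8)
    bins = np.asarray(bins)
    bin_means = np.array([ys[xs == b].mean() if np.any(xs == b) else np.nan
                          for b in bins])
    bin_se = np.array([ys[xs == b].std(ddof=1) / np.sqrt((xs == b).sum())
                       if (xs == b).sum() > 1 else np.nan for b in bins])
    bin_n = np.array([(xs == b).sum() for b in bins])
    ok = (bin_n > 1) & (bin_means > 0)  # zero-mean bins cannot be logged
    if ok.sum() < 3:
        raise ValueError("need at least 3 occupied, non-zero TC-count bins")
    lx, ly = np.log(bins[ok].astype(float)), np.log(bin_means[ok])
    # delta-method error of the log bin mean weights the fit and its CI
    se_log = np.clip(bin_se[ok] / bin_means[ok], 1e-6, None)
    import statsmodels.api as sm
    res = sm.WLS(ly, sm.add_constant(lx), weights=1.0 / se_log**2).fit()
    ci = res.conf_int(alpha=0.05)
    return ScalingFit(exponent=float(res.params[1]),
                      intercept=float(res.params[0]),
                      ci95=(float(ci[1][0]), float(ci[1][1])),
                      r2=float(res.rsquared), mode=mode, phase=phase,
                      bins=bins[ok], bin_means=bin_means[ok], bin_n=bin_n[ok])


# ---------------------------------------------------------------------------
# correlations


def _safe_corr(a, b):
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def correlations(counts: TrialCounts, table: pd.DataFrame) -> pd.DataFrame:
    """Trial-wise auto- and cross-correlations per responder class.

    Per (TC, cell): Pearson correlation across trials of base' vs base
    (ongoing temporal order) and base vs resp (response predictability), plus
    cross-correlations of the TC's window count with the cell's count in the
    same phase.  Values are averaged within each class; the TC itself is
    reported as class 'TC'.
    """
    rows = []
    for tc in counts.tcs:
        tr = counts.trials_of(tc)
        sub = table[table["tc"] == tc]
        cls_of = dict(zip(sub["cell"], sub["cls"]))
        cls_of[tc] = "TC"
        for cell, cls in cls_of.items():
            rows.append({
                "tc": tc, "cell": cell, "cls": cls,
                "r_base": _safe_corr(counts.base_prime[tr, cell],
                                     counts.base[tr, cell]),
                "r_resp": _safe_corr(counts.base[tr, cell],
                                     counts.resp[tr, cell]),
                "cc_base": _safe_corr(counts.base[tr, tc],
                                      counts.base[tr, cell])
                if cell != tc else np.nan,
                "cc_stim": _safe_corr(counts.resp[tr, tc],
                                      counts.resp[tr, cell])
                if cell != tc else np.nan,
            })
    per_cell = pd.DataFrame(rows)
    summary = per_cell.groupby("cls")[["r_base", "r_resp", "cc_base",
                                       "cc_stim"]].mean()
    summary.attrs["per_cell"] = per_cell
    return summary


# ---------------------------------------------------------------------------
# Fano factors


def _ff(x):
    m = x.mean()
    return np.nan if m == 0 else x.var(ddof=1) / m


def fano(counts: TrialCounts, matched: bool = True,
         max_window: int = 9, mismatch_limit: float = 0.2) -> pd.DataFrame:
    """Mean-matched Fano factors per (TC, cell).

    The stimulus-window length (1..max_window frames from onset) is chosen to
    minimise the normalised difference between mean stimulus and mean
    baseline count; cells whose best window still mismatches by more than
    ``mismatch_limit`` are excluded.  The 6-frame uncorrected stimulus FF is
    also reported.  With ``matched=False`` the fixed 6-frame window is used
    throughout.
    """
    rec = counts.rec
    w = counts.window_frames
    stim_by_len = [window_counts(rec, counts.onset_frames, 0, L)
                   for L in range(1, max_window + 1)]
    rows = []
    non_tc = np.setdiff1d(np.arange(rec.n_cells), rec.tc_indices)
    for tc in counts.tcs:
        tr = counts.trials_of(tc)
        for cell in np.concatenate(([tc], non_tc)):
            b = counts.base[tr, cell]
            mb = b.mean()
            ff_unc = _ff(counts.resp[tr, cell])
            if mb == 0:
                rows.append({"tc": tc, "cell": cell, "is_tc": cell == tc,
                             "ff_base": np.nan, "ff_stim": np.nan,
                             "ff_stim_uncorrected": ff_unc,
                             "window_len": 0, "mismatch": np.nan,
                             "excluded": True})
                continue
            if matched:
                mism = np.array([abs(sl[tr, cell].mean() - mb) / mb
                                 for sl in stim_by_len])
                li = int(np.argmin(mism))
                best = mism[li]
            else:
                li, best = w - 1, abs(stim_by_len[w - 1][tr, cell].mean() - mb) / mb
            s = stim_by_len[li][tr, cell]
            rows.append({"tc": tc, "cell": cell, "is_tc": cell == tc,
                         "ff_base": _ff(b), "ff_stim": _ff(s),
                         "ff_stim_uncorrected": ff_unc,
                         "window_len": li + 1, "mismatch": best,
                         "excluded": matched and best > mismatch_limit})
    out = pd.DataFrame(rows)
    # population-level FF: variance/mean across trials of the summed non-TC count
    pop = []
    for tc in counts.tcs:
        tr = counts.trials_of(tc)
        pop.append({"tc": tc,
                    "ff_base_pop": _ff(counts.base[tr][:, non_tc].sum(axis=1)),
                    "ff_stim_pop": _ff(counts.resp[tr][:, non_tc].sum(axis=1))})
    out.attrs["population"] = pd.DataFrame(pop)
    return out


# ---------------------------------------------------------------------------
# trial splits and regimes


def split_trials(counts: TrialCounts, criterion: str) -> dict:
    """Trial masks for control splits.

    ``'tc_count'``: per TC, the 91st percentile of its baseline counts sets a
    threshold thr; 'low' trials have response count in (thr, 2*thr], 'high'
    trials exceed 2*thr.  ``'baseline'``: trials below the 25th / above the
    75th percentile of the population baseline count (per TC group).
    ``'timing'``: returns the early/late 6-frame windows around the TC's mean
    response peak (adjacent, non-overlapping) rather than masks.  Percentile
    ties go to the lower subset.
    """
    n = counts.n_trials
    if criterion == "tc_count":
        low = np.zeros(n, dtype=bool)
        high = np.zeros(n, dtype=bool)
        for tc in counts.tcs:
            tr = counts.trials_of(tc)
            thr = np.percentile(counts.base[tr, tc], 91)
            r = counts.resp[tr, tc]
            low[tr] = (r > thr) & (r <= 2 * thr)
            high[tr] = r > 2 * thr
        return {"low": low, "high": high}
    if criterion == "baseline":
        non_tc = np.setdiff1d(np.arange(counts.rec.n_cells),
                              counts.rec.tc_indices)
        low = np.zeros(n, dtype=bool)
        high = np.zeros(n, dtype=bool)
        for tc in counts.tcs:
            tr = counts.trials_of(tc)
            popbase = counts.base[tr][:, non_tc].sum(axis=1)
            low[tr] = popbase < np.percentile(popbase, 25)
            high[tr] = popbase > np.percentile(popbase, 75)
        return {"low": low, "high": high}
    if criterion == "timing":
        w = counts.window_frames
        out = {}
        for tc in counts.tcs:
            tr = counts.trials_of(tc)
            prof = np.zeros(w)
            for off in range(w):
                prof[off] = window_counts(counts.rec,
                                          counts.onset_frames[tr], off,
                                          1)[:, tc].mean()
            peak = int(np.argmax(prof))
            early = (peak - w + 1, peak + 1)   # 6-frame window ending at peak
            late = (peak + 1, peak + w + 1)    # adjacent 6-frame window
            out[tc] = {"peak_offset": peak, "early": early, "late": late}
        return out
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class BaselineRegimeScaling:
    cell_base: np.ndarray
    cell_resp: np.ndarray
    bin_edges: np.ndarray
    bin_base: np.ndarray
    bin_resp: np.ndarray
    labels: dict              # theta -> per-cell 'LOW'/'HIGH' labels
    slope_low: dict           # theta -> regression slope within LOW cells
    slope_high: dict


def baseline_regime_scaling(counts: TrialCounts, theta_grid=(0.3,),
                            n_bins: int = 10) -> BaselineRegimeScaling:
    """Mean response vs mean baseline count across non-TC cells.

    Cells are binned by their mean baseline count; for every theta in the
    grid, cells are labelled LOW (mean base < theta) or HIGH and a linear
    regression of mean response on mean baseline is run per regime.
    """
    non_tc = np.setdiff1d(np.arange(counts.rec.n_cells), counts.rec.tc_indices)
    cb = counts.base[:, non_tc].mean(axis=0)
    cr = counts.resp[:, non_tc].mean(axis=0)
    edges = np.quantile(cb, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    which = np.clip(np.searchsorted(edges, cb, side="right") - 1,
                    0, len(edges) - 2)
    bin_base = np.array([cb[which == i].mean() if np.any(which == i) else np.nan
                         for i in range(len(edges) - 1)])
    bin_resp = np.array([cr[which == i].mean() if np.any(which == i) else np.nan
                         for i in range(len(edges) - 1)])
    labels, slo, shi = {}, {}, {}
    for theta in theta_grid:
        lab = np.where(cb < theta, "LOW", "HIGH")
        labels[theta] = lab
        for name, store in (("LOW", slo), ("HIGH", shi)):
            sel = lab == name
            store[theta] = float(np.polyfit(cb[sel], cr[sel], 1)[0]) \
                if sel.sum() >= 3 and cb[sel].std() > 0 else np.nan
    return BaselineRegimeScaling(cb, cr, edges, bin_base, bin_resp,
                                 labels, slo, shi)


def responder_distance_profile(table: pd.DataFrame, rec: Recording,
                               radii) -> pd.DataFrame:
    """Fraction of cells classified PosR per radial annulus around each TC,
    averaged over TCs; empty annuli yield NaN."""
    radii = np.asarray(radii, dtype=float)
    per_tc = []
    for tc in table["tc"].unique():
        sub = table[table["tc"] == tc]
        cells = sub["cell"].to_numpy()
        d = np.hypot(*(rec.positions[cells] - rec.positions[int(tc)]).T)
        is_pos = (sub["cls"] == "PosR").to_numpy()
        fr = []
        for lo, hi in zip(radii[:-1], radii[1:]):
            sel = (d >= lo) & (d < hi)
            fr.append(is_pos[sel].mean() if sel.any() else np.nan)
        per_tc.append(fr)
    arr = np.asarray(per_tc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_frac = np.nanmean(arr, axis=0)
    return pd.DataFrame({"r_lo": radii[:-1], "r_hi": radii[1:],
                         "frac_posr": mean_frac,
                         "n_tc_defined": np.sum(~np.isnan(arr), axis=0)})
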