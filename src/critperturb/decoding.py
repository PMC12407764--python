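"""Decoding the origin of a perturbation from non-target population activity.

Target cells are the classes, non-target spike counts the features.  Two
tree-ensemble classifiers (gradient-boosted trees via XGBoost, random forest
via scikit-learn) are evaluated over repeated stratified 80/20 splits;
feature relevance is probed by Shapley-ranked iterative neuron elimination,
spatial exclusion zones, single-frame temporal profiles and baseline
pseudo-trial decoding.

Shapley attributions for the boosted model come from XGBoost's built-in
TreeSHAP (``pred_contribs``); the random forest falls back to impurity-based
importances with a warning, since no exact tree-Shapley backend is available
for it here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import train_test_split
import xgboost as xgb

from .recording import Recording
from .response import window_counts

DEFAULT_TREES = 500
DEFAULT_DEPTH = 6


@dataclass
class DecodingDataset:
    """Feature matrix (trials x non-TC cells) with TC labels."""

    X: np.ndarray
    y: np.ndarray                 # TC cell index per trial
    feature_cells: np.ndarray     # cell row per feature column
    trial_index: np.ndarray       # rows of the recording's trial table kept
    window_frames: int
    offset_frames: int
    filtered: bool

    def __post_init__(self):
        if len(np.unique(self.y)) < 2:
            raise ValueError("need at least two TC classes for decoding")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def chance(self) -> float:
        return 1.0 / len(self.classes)

    def drop_features(self, cells) -> "DecodingDataset":
        keep = ~np.isin(self.feature_cells, np.asarray(cells))
        return DecodingDataset(self.X[:, keep], self.y,
                               self.feature_cells[keep], self.trial_index,
                               self.window_frames, self.offset_frames,
                               self.filtered)


def build_dataset(rec: Recording, window_frames: int = 6,
                  offset_frames: int = 0, filtered: bool = True,
                  min_tc_spike_frac: float = 0.5) -> DecodingDataset:
    """Construct the decoding dataset from a Recording.

    Features are non-TC spike counts in a window of ``window_frames`` frames
    offset by ``offset_frames`` from each trial onset.  When ``filtered``,
    trials whose TC fired no spike in the 6-frame response window are
    dropped, and TCs that spiked in fewer than half of their trials are
    removed entirely.
    """
    if rec.trials is None or not len(rec.trials):
        raise ValueError("recording has no trials")
    onsets = rec.trials["onset_frame"].to_numpy(dtype=int)
    tcs = rec.trials["tc"].to_numpy(dtype=int)
    lo = min(offset_frames, 0)
    hi = max(offset_frames + window_frames, 6)
    ok = (onsets + lo >= 0) & (onsets + hi <= rec.n_frames)
    onsets, tcs = onsets[ok], tcs[ok]
    trial_rows = np.flatnonzero(ok)

    keep = np.ones(len(onsets), dtype=bool)
    if filtered:
        resp = window_counts(rec, onsets, 0, 6)
        tc_spikes = resp[np.arange(len(onsets)), tcs]
        spiked = tc_spikes >= 1
        valid_tcs = [tc for tc in np.unique(tcs)
                     if spiked[tcs == tc].mean() >= min_tc_spike_frac]
        keep = spiked & np.isin(tcs, valid_tcs)
    X_all = window_counts(rec, onsets[keep], offset_frames, window_frames)
    feature_cells = rec.non_tc_indices
    return DecodingDataset(X_all[:, feature_cells].astype(float), tcs[keep],
                           feature_cells, trial_rows[keep], window_frames,
                           offset_frames, filtered)


def make_model(kind: str = "gbt", seed: int = 0,
               n_estimators: int = DEFAULT_TREES,
               max_depth: int = DEFAULT_DEPTH):
    if kind == "gbt":
        return xgb.XGBClassifier(n_estimators=n_estimators,
                                 max_depth=max_depth, learning_rate=0.3,
                                 tree_method="hist", n_jobs=1,
                                 random_state=seed, verbosity=0)
    if kind == "rf":
        return RandomForestClassifier(n_estimators=n_estimators, n_jobs=1,
                                      random_state=seed)
    raise ValueError(f"unknown model kind {kind!r}")


def _encode(y, classes):
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y])


def _fit_predict(ds, train, test, kind, seed, n_estimators, max_depth):
    model = make_model(kind, seed, n_estimators, max_depth)
    classes = ds.classes
    model.fit(ds.X[train], _encode(ds.y[train], classes))
    pred = model.predict(ds.X[test])
    return model, classes[pred]


@dataclass
class DecodingResult:
    accuracy: np.ndarray          # per repetition
    f1: pd.DataFrame              # per (repetition, class)
    model_kind: str
    n_splits: int
    chance: float

    @property
    def accuracy_mean(self):
        return float(self.accuracy.mean())

    @property
    def accuracy_se(self):
        return float(self.accuracy.std(ddof=1) / np.sqrt(len(self.accuracy))) \
            if len(self.accuracy) > 1 else np.nan

    def summary(self) -> dict:
        return {"accuracy": self.accuracy_mean, "accuracy_se": self.accuracy_se,
                "f1_macro": float(self.f1["f1"].mean()),
                "chance": self.chance, "model": self.model_kind,
                "n_splits": self.n_splits}


def train_eval(ds: DecodingDataset, model: str = "gbt", n_splits: int = 100,
               test_frac: float = 0.2, seed: int = 0, stratified: bool = True,
               n_estimators: int = DEFAULT_TREES,
               max_depth: int = DEFAULT_DEPTH) -> DecodingResult:
    """Repeated random-split evaluation (80/20 by default).

    Splits are stratified per class unless ``stratified=False``; overall
    accuracy and per-class precision/recall/F1 are averaged over splits, with
    the chance level 1/n_classes recorded.
    """
    rng = np.random.default_rng(seed)
    accs = np.empty(n_splits)
    f1_rows = []
    idx = np.arange(len(ds.y))
    for rep in range(n_splits):
        rs = int(rng.integers(0, 2**31 - 1))
        train, test = train_test_split(
            idx, test_size=test_frac, random_state=rs,
            stratify=ds.y if stratified else None)
        _, pred = _fit_predict(ds, train, test, model, rs, n_estimators,
                               max_depth)
        accs[rep] = np.mean(pred == ds.y[test])
        pr, rc, f1, _ = precision_recall_fscore_support(
            ds.y[test], pred, labels=ds.classes, zero_division=0)
        for c, p_, r_, f_ in zip(ds.classes, pr, rc, f1):
            f1_rows.append({"rep": rep, "tc": c, "precision": p_,
                            "recall": r_, "f1": f_})
    return DecodingResult(accs, pd.DataFrame(f1_rows), model, n_splits,
                          ds.chance)


# ---------------------------------------------------------------------------
# Shapley-guided neuron elimination


def _importance(model, X, kind):
    """Mean |Shapley| attribution per feature (TreeSHAP for the boosted
    model); falls back to impurity importance for the forest."""
    if kind == "gbt":
        contrib = model.get_booster().predict(xgb.DMatrix(X),
                                              pred_contribs=True)
        contrib = np.asarray(contrib)
        if contrib.ndim == 3:          # multiclass: (n, class, feat+1)
            imp = np.abs(contrib[:, :, :-1]).mean(axis=(0, 1))
        else:
            imp = np.abs(contrib[:, :-1]).mean(axis=0)
        return imp
    warnings.warn("no tree-Shapley backend for this model; using impurity "
                  "importances")
    return np.asarray(model.feature_importances_)


@dataclass
class DropCurve:
    """Iterative feature-elimination curves.

    ``order[rep, i]`` is the cell removed at step i of repetition rep;
    ``accuracy[rep, i]`` the test accuracy with i features removed (column 0
    = full model), similarly ``f1_macro``.
    """

    order: np.ndarray
    accuracy: np.ndarray
    f1_macro: np.ndarray
    model_kind: str
    feature_cells: np.ndarray
    chance: float


def shapley_drop(ds: DecodingDataset, model: str = "gbt", repeats: int = 10,
                 test_frac: float = 0.2, seed: int = 0,
                 n_estimators: int = DEFAULT_TREES,
                 max_depth: int = DEFAULT_DEPTH,
                 drop_per_iter: int = 1) -> DropCurve:
    """Sequential elimination of the highest-Shapley-ranked features.

    Per iteration the model is trained, test metrics recorded, features
    ranked by mean |attribution| on the training fold, and the top
    ``drop_per_iter`` features removed; repeated until one feature remains.
    Importance ties break deterministically by cell index.
    """
    rng = np.random.default_rng(seed)
    n_feat = ds.X.shape[1]
    n_iter = int(np.ceil((n_feat - 1) / drop_per_iter))
    order = np.full((repeats, n_feat - 1), -1, dtype=int)
    acc = np.full((repeats, n_iter + 1), np.nan)
    f1m = np.full((repeats, n_iter + 1), np.nan)
    idx = np.arange(len(ds.y))
    for rep in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        train, test = train_test_split(idx, test_size=test_frac,
                                       random_state=rs, stratify=ds.y)
        cur = ds
        removed = 0
        for it in range(n_iter + 1):
            mod, pred = _fit_predict(cur, train, test, model, rs,
                                     n_estimators, max_depth)
            acc[rep, it] = np.mean(pred == cur.y[test])
            _, _, f1, _ = precision_recall_fscore_support(
                cur.y[test], pred, labels=cur.classes, zero_division=0)
            f1m[rep, it] = f1.mean()
            if cur.X.shape[1] <= 1 or it == n_iter:
                break
            imp = _importance(mod, cur.X[train], model)
            n_drop = min(drop_per_iter, cur.X.shape[1] - 1)
            # ties -> lower cell index first (stable sort on -importance)
            rank = np.argsort(-imp, kind="stable")[:n_drop]
            cells = cur.feature_cells[rank]
            order[rep, removed:removed + n_drop] = cells
            removed += n_drop
            cur = cur.drop_features(cells)
    return DropCurve(order, acc, f1m, model, ds.feature_cells, ds.chance)


def posr_drop_probability(curve: DropCurve, table: pd.DataFrame) -> pd.DataFrame:
    """L(rank): probability that the cell removed at each rank is a PosR,
    averaged over TCs and repetitions."""
    is_pos = {(int(t), int(c)): cls == "PosR"
              for t, c, cls in zip(table["tc"], table["cell"], table["cls"])}
    tcs = table["tc"].unique()
    n_rank = curve.order.shape[1]
    L = np.zeros(n_rank)
    for r in range(n_rank):
        vals = []
        for rep in range(curve.order.shape[0]):
            cell = curve.order[rep, r]
            if cell < 0:
                continue
            vals.extend(float(is_pos.get((int(tc), int(cell)), False))
                        for tc in tcs)
        L[r] = np.mean(vals) if vals else np.nan
    return pd.DataFrame({"rank": np.arange(1, n_rank + 1), "L": L})


# ---------------------------------------------------------------------------
# spatial, temporal, baseline analyses


@dataclass
class RadiusResult:
    radius_grid: np.ndarray
    f1_per_tc: pd.DataFrame       # columns tc, radius, f1
    p_excluded: np.ndarray        # exclusion probability profile over radii
    critical_radius: float
    critical_radius_per_tc: dict


def radius_exclusion(rec: Recording, radius_grid, model: str = "gbt",
                     n_splits: int = 10, seed: int = 0,
                     n_estimators: int = DEFAULT_TREES,
                     max_depth: int = DEFAULT_DEPTH,
                     smooth_sigma: float = 1.0, **ds_kw) -> RadiusResult:
    """Exclusion-zone analysis: remove features within r of the evaluated TC,
    retrain, and track that TC's F1.

    The critical radius per TC is the first radius at which the change in the
    (Gaussian-smoothed, sigma = 1 grid step) F1 curve drops more than three
    standard deviations below its mean rate of change; radius 0 reproduces
    the full-feature F1 exactly.
    """
    radius_grid = np.asarray(radius_grid, dtype=float)
    ds = build_dataset(rec, **ds_kw)
    rows = []
    n_excl = np.zeros(len(radius_grid))
    for tc in ds.classes:
        d = np.hypot(*(rec.positions[ds.feature_cells]
                       - rec.positions[int(tc)]).T)
        for i, r in enumerate(radius_grid):
            n_excl[i] += (d < r).sum()
            if r > 0 and (d < r).all():
                # every feature removed: decoding collapses to chance
                rows.append({"tc": tc, "radius": r, "f1": ds.chance})
                continue
            sub = ds.drop_features(ds.feature_cells[d < r]) if r > 0 else ds
            res = train_eval(sub, model=model, n_splits=n_splits, seed=seed,
                             n_estimators=n_estimators, max_depth=max_depth)
            f1_tc = res.f1.loc[res.f1["tc"] == tc, "f1"].mean()
            rows.append({"tc": tc, "radius": r, "f1": float(f1_tc)})
    f1_df = pd.DataFrame(rows)
    p_ex = n_excl / n_excl[-1] if n_excl[-1] > 0 else n_excl
    crit = {}
    for tc in ds.classes:
        f1 = f1_df.loc[f1_df["tc"] == tc, "f1"].to_numpy()
        sm = gaussian_filter1d(f1, smooth_sigma)
        diff = np.diff(sm)
        if len(diff) and diff.std() > 0:
            thr = diff.mean() - 3 * diff.std()
            hit = np.flatnonzero(diff < thr)
            crit[int(tc)] = float(radius_grid[hit[0] + 1]) if len(hit) else np.nan
        else:
            crit[int(tc)] = np.nan
    vals = [v for v in crit.values() if np.isfinite(v)]
    return RadiusResult(radius_grid, f1_df, p_ex,
                        float(np.mean(vals)) if vals else np.nan, crit)


def temporal_profile(rec: Recording, window_frames: int = 1,
                     offsets=range(-10, 15), model: str = "gbt",
                     n_splits: int = 10, seed: int = 0,
                     n_estimators: int = DEFAULT_TREES,
                     max_depth: int = DEFAULT_DEPTH) -> pd.DataFrame:
    """Decoding accuracy versus response-window offset (frames, unfiltered).

    Offset 0 is the first window fully overlapping the stimulation (the
    onset frame).  Offsets whose windows fall outside the recording for some
    trial are skipped.
    """
    rows = []
    for off in offsets:
        try:
            ds = build_dataset(rec, window_frames=window_frames,
                               offset_frames=int(off), filtered=False)
        except (ValueError,):
            continue
        res = train_eval(ds, model=model, n_splits=n_splits, seed=seed,
                         n_estimators=n_estimators, max_depth=max_depth)
        rows.append({"offset": int(off), "accuracy": res.accuracy_mean,
                     "se": res.accuracy_se, "chance": res.chance})
    return pd.DataFrame(rows)


def baseline_pseudotrials(rec: Recording, ds_stim: DecodingDataset,
                          window_frames: int = 6, margin_windows: int = 1,
                          seed: int = 0) -> DecodingDataset:
    """Pseudo-trials from inter-trial activity where exactly one TC spiked.

    The recording is segmented into non-overlapping 6-frame bins; bins within
    ``margin_windows`` windows of any stimulation response window are
    excluded; bins in which exactly one of the decoded TCs spiked become
    pseudo-trials labelled by that TC, downsampled per class to match the
    class histogram of the stimulation dataset.
    """
    w = window_frames
    n_bins = rec.n_frames // w
    starts = np.arange(n_bins) * w
    tcs = ds_stim.classes
    onsets = rec.trials["onset_frame"].to_numpy(dtype=int)
    excl = np.zeros(n_bins, dtype=bool)
    for f0 in onsets:
        lo = f0 - margin_windows * w
        hi = f0 + w + margin_windows * w
        excl |= (starts + w > lo) & (starts < hi)
    bin_counts = window_counts(rec, starts[~excl], 0, w)
    tc_counts = bin_counts[:, tcs]
    one_tc = (tc_counts >= 1).sum(axis=1) == 1
    labels = tcs[np.argmax(tc_counts[one_tc] >= 1, axis=1)]
    feats = bin_counts[one_tc][:, ds_stim.feature_cells].astype(float)
    kept_bins = np.flatnonzero(~excl)[one_tc]

    # downsample to the stimulation class histogram
    rng = np.random.default_rng(seed)
    want = {tc: int((ds_stim.y == tc).sum()) for tc in tcs}
    sel = []
    for tc in tcs:
        pool = np.flatnonzero(labels == tc)
        take = min(len(pool), want[tc])
        sel.extend(rng.choice(pool, size=take, replace=False))
    sel = np.sort(np.asarray(sel, dtype=int))
    return DecodingDataset(feats[sel], labels[sel], ds_stim.feature_cells,
                           kept_bins[sel], w, 0, False)


def regime_split_decoding(rec: Recording, theta_grid, model: str = "gbt",
                          n_splits: int = 10, seed: int = 0,
                          n_estimators: int = DEFAULT_TREES,
                          max_depth: int = DEFAULT_DEPTH,
                          **ds_kw) -> pd.DataFrame:
    """Decoding accuracy for LOW vs HIGH population-baseline trials.

    Trials are partitioned by the summed non-TC baseline count against each
    theta; partitions are disjoint and exhaustive.  Partitions with fewer
    than two classes or fewer than 5 trials per class are reported as NaN.
    """
    ds = build_dataset(rec, **ds_kw)
    onsets = rec.trials["onset_frame"].to_numpy(dtype=int)[ds.trial_index]
    base = window_counts(rec, onsets, -12, 6)[:, ds.feature_cells].sum(axis=1)
    rows = []
    for theta in np.asarray(theta_grid, dtype=float):
        res = {}
        for name, mask in (("low", base < theta), ("high", base >= theta)):
            ok = mask.sum() >= 10
            if ok:
                ys = ds.y[mask]
                classes, cnt = np.unique(ys, return_counts=True)
                ok = len(classes) >= 2 and cnt.min() >= 5
            if not ok:
                res[name] = np.nan
                continue
            sub = DecodingDataset(ds.X[mask], ds.y[mask], ds.feature_cells,
                                  ds.trial_index[mask], ds.window_frames,
                                  ds.offset_frames, ds.filtered)
            r = train_eval(sub, model=model, n_splits=n_splits, seed=seed,
                           n_estimators=n_estimators, max_depth=max_depth)
            res[name] = r.accuracy_mean
        rows.append({"theta": theta, "acc_low": res["low"],
                     "acc_high": res["high"],
                     "difference": res["low"] - res["high"]})
    return pd.DataFrame(rows)
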