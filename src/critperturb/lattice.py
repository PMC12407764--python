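"""2D excitable-lattice network: construction, dynamics, calibration, protocol.

The model is a lattice of excitable units (rest / active / refractory) with
distance-dependent directed connectivity on a torus,

    Pconn(r) = g_amp * exp(-r^2 / (2 * g_scale^2)) + e_amp * exp(-r / e_scale),

per-edge transmission probability ``p_trans = sigma / k_bar`` (sigma is the
branching parameter, k_bar the measured mean out-degree), and a homogeneous
external Poisson drive ``p_poiss`` per unit per 2-ms step.  Tuning sigma
through ~1 moves the network across a directed-percolation-style phase
transition between activity that fades (subcritical) and activity that
self-sustains (supercritical).

The module also provides the stimulation protocol used to probe the network
(repeated extra drive onto target cells, TCs), frame binning into recordings
that mimic two-photon spike rasters, drive-response curves, a
survival-probability locator for the critical point, and the structural
output-strength measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _core
from .recording import Recording

REST, ACTIVE, REFRACTORY = _core.REST, _core.ACTIVE, _core.REFRACTORY

DEFAULT_STEP_MS = 2.0
DEFAULT_FRAME_MS = 22.0
FOV_SIDE = 38  # central analysis block, 38 x 38 units


class ParameterError(ValueError):
    """A model parameter is outside its valid range."""


class CalibrationInfeasibleError(RuntimeError):
    """The requested operating point cannot be reached by calibration."""


# ---------------------------------------------------------------------------
# network construction


def _offset_probabilities(side, spacing_um, gauss_amp, gauss_scale_um,
                          exp_amp, exp_scale_um, max_radius_um=None):
    d = np.arange(side)
    t = np.minimum(d, side - d) * spacing_um  # torus displacement, per axis
    r = np.hypot(t[:, None], t[None, :])
    p = gauss_amp * np.exp(-r**2 / (2.0 * gauss_scale_um**2)) \
        + exp_amp * np.exp(-r / exp_scale_um)
    p[0, 0] = 0.0
    if max_radius_um is not None:
        p[r > max_radius_um] = 0.0
    if np.any(p > 1.0):
        raise ParameterError("connection probability exceeds 1 at some offset")
    return p, r


def expected_out_degree(side=300, spacing_um=12.0, gauss_amp=0.05,
                        gauss_scale_um=100.0, exp_amp=0.03,
                        exp_scale_um=290.0, max_radius_um=None):
    """Analytic expected out-degree: the sum of Pconn over all torus offsets."""
    p, _ = _offset_probabilities(side, spacing_um, gauss_amp, gauss_scale_um,
                                 exp_amp, exp_scale_um, max_radius_um)
    return float(p.sum())


@dataclass(frozen=True)
class LatticeNetwork:
    """Directed excitable network on a periodic 2D lattice."""

    side: int
    spacing_um: float
    adjacency: sp.csr_matrix  # boolean, row = presynaptic unit
    k_bar: float
    rng_seed: int
    sigma: float | None = None
    p_trans: float = 0.0
    p_poiss: float = 0.0
    refractory_steps: int = 1
    periodic: bool = True

    @property
    def n_units(self) -> int:
        return self.side * self.side

    @property
    def positions(self) -> np.ndarray:
        """Unit coordinates in micrometres, (n_units, 2)."""
        idx = np.arange(self.n_units)
        return np.column_stack((idx // self.side, idx % self.side)
                               ).astype(float) * self.spacing_um

    @property
    def fov_side(self) -> int:
        return min(FOV_SIDE, self.side)

    @property
    def fov_indices(self) -> np.ndarray:
        """Unit indices of the central fov_side x fov_side analysis block."""
        s = self.fov_side
        lo = (self.side - s) // 2
        rows = np.arange(lo, lo + s)
        return (rows[:, None] * self.side + rows[None, :]).ravel()

    def torus_distance(self, i, j) -> np.ndarray:
        """Periodic Euclidean distance in micrometres between unit indices."""
        i = np.asarray(i)
        j = np.asarray(j)
        dx = np.abs(i // self.side - j // self.side)
        dy = np.abs(i % self.side - j % self.side)
        dx = np.minimum(dx, self.side - dx) * self.spacing_um
        dy = np.minimum(dy, self.side - dy) * self.spacing_um
        return np.hypot(dx, dy)


def build_lattice(side=300, spacing_um=12.0, gauss_amp=0.05,
                  gauss_scale_um=100.0, exp_amp=0.03, exp_scale_um=290.0,
                  max_radius_um=None, refractory_steps=1, seed=0) -> LatticeNetwork:
    """Sample a directed lattice network with distance-dependent connectivity.

    Each ordered pair (i, j), i != j, is connected independently with
    probability Pconn(r_ij) evaluated at the torus distance.  ``max_radius_um``
    optionally truncates connections beyond a radius (off by default; the mean
    out-degree is always the measured one).
    """
    if side < 2:
        raise ParameterError("side must be >= 2")
    for a in (gauss_amp, exp_amp):
        if not 0.0 <= a <= 1.0:
            raise ParameterError("amplitudes must lie in [0, 1]")
    if gauss_scale_um <= 0 or exp_scale_um <= 0:
        raise ParameterError("scales must be positive")

    p, _ = _offset_probabilities(side, spacing_um, gauss_amp, gauss_scale_um,
                                 exp_amp, exp_scale_um, max_radius_um)
    n = side * side
    p_flat = p.ravel()

    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    src, off = _sample_edges(p_flat, n, kernel_seed)
    dx = off // side
    dy = off % side
    sx = src // side
    sy = src % side
    tgt = ((sx + dx) % side) * side + ((sy + dy) % side)
    adj = sp.coo_matrix(
        (np.ones(len(src), dtype=np.int8), (src, tgt)), shape=(n, n)
    ).tocsr()
    k_bar = adj.nnz / n
    return LatticeNetwork(side=side, spacing_um=spacing_um, adjacency=adj,
                          k_bar=float(k_bar), rng_seed=seed,
                          refractory_steps=refractory_steps)


def _sample_edges(p_flat, n, seed):
    return _core.sample_edges(p_flat, n, seed)


def set_branching(net: LatticeNetwork, sigma: float) -> LatticeNetwork:
    """Set the branching parameter; stores p_trans = sigma / k_bar."""
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    if sigma == 0:
        return replace(net, sigma=0.0, p_trans=0.0)
    if net.k_bar <= 0:
        raise ParameterError("network has no edges; sigma > 0 is meaningless")
    p_trans = sigma / net.k_bar
    if p_trans > 1.0:
        raise ParameterError(
            f"sigma/k_bar = {p_trans:.3g} exceeds 1; not a probability")
    return replace(net, sigma=float(sigma), p_trans=float(p_trans))


# ---------------------------------------------------------------------------
# dynamics


@dataclass
class SimState:
    """Per-unit automaton state plus refractory timers."""

    state: np.ndarray        # int8, REST/ACTIVE/REFRACTORY
    refr_timer: np.ndarray   # int32, remaining refractory steps
    step_index: int = 0

    @classmethod
    def resting(cls, n_units: int) -> "SimState":
        return cls(np.zeros(n_units, dtype=np.int8),
                   np.zeros(n_units, dtype=np.int32))


def step(net: LatticeNetwork, sim: SimState, rng: np.random.Generator,
         stim_prob: np.ndarray | None = None):
    """One synchronous update (NumPy reference implementation).

    Each resting unit activates with probability
    ``1 - (1-p_poiss) * (1-p_stim_i) * (1-p_trans)^m_i`` where ``m_i`` counts
    active presynaptic neighbours; transmitters then enter refractoriness.
    Returns the new SimState and the indices of newly active units.
    """
    state = sim.state
    n = net.n_units
    active = state == ACTIVE
    if active.any() and net.p_trans > 0:
        m = np.asarray(net.adjacency[active].sum(axis=0)).ravel()
    else:
        m = np.zeros(n)
    p_fail = (1.0 - net.p_poiss) * (1.0 - net.p_trans) ** m
    if stim_prob is not None:
        p_fail = p_fail * (1.0 - np.asarray(stim_prob, dtype=float))
    activated = (state == REST) & (rng.random(n) < 1.0 - p_fail)

    new_state = state.copy()
    timer = sim.refr_timer.copy()
    old_refr = state == REFRACTORY
    timer[old_refr] -= 1
    new_state[old_refr & (timer <= 0)] = REST
    if net.refractory_steps > 0:
        new_state[active] = REFRACTORY
        timer[active] = net.refractory_steps
    else:
        new_state[active] = REST
    new_state[activated] = ACTIVE
    return SimState(new_state, timer, sim.step_index + 1), np.flatnonzero(activated)


@dataclass
class SimulationRun:
    """Raw output of a kernel run."""

    ev_step: np.ndarray      # spike event step indices (recorded channels)
    ev_channel: np.ndarray   # recording-channel index per event
    active_counts: np.ndarray
    final_state: np.ndarray
    channel_units: np.ndarray  # global unit id per channel
    n_steps: int
    record_from: int


def run_lattice(net: LatticeNetwork, n_steps: int, p_poiss: float | None = None,
                seed: int = 0, init_state: np.ndarray | None = None,
                stim_units=None, stim_onsets=None, stim_len: int = 0,
                p_stim: float = 0.0, record_units=None,
                record_from: int = 0) -> SimulationRun:
    """Drive the numba kernel; spikes of ``record_units`` are stored as events."""
    n = net.n_units
    q = net.p_poiss if p_poiss is None else float(p_poiss)
    state0 = np.zeros(n, dtype=np.int8) if init_state is None \
        else np.asarray(init_state, dtype=np.int8)
    if record_units is None:
        record_units = np.empty(0, dtype=np.int64)
    record_units = np.asarray(record_units, dtype=np.int64)
    fov_local = np.full(n, -1, dtype=np.int32)
    fov_local[record_units] = np.arange(len(record_units), dtype=np.int32)
    su = np.asarray(stim_units if stim_units is not None else [], dtype=np.int64)
    so = np.asarray(stim_onsets if stim_onsets is not None else [], dtype=np.int64)
    ev_s, ev_u, counts, final = _core.simulate(
        net.adjacency.indptr, net.adjacency.indices, n, float(net.p_trans),
        q, int(net.refractory_steps), int(n_steps), state0, su, so,
        int(stim_len), float(p_stim), fov_local, int(record_from),
        int(seed) % (2**31 - 1))
    return SimulationRun(ev_s, ev_u, counts, final, record_units,
                         int(n_steps), int(record_from))


# ---------------------------------------------------------------------------
# frame binning


def bin_to_frames(step_raster: np.ndarray, frame_ms: float = DEFAULT_FRAME_MS,
                  step_ms: float = DEFAULT_STEP_MS,
                  onset_steps=None):
    """Sum a (units x steps) binary raster into non-overlapping frames.

    The incomplete tail frame is dropped; spike counts are conserved over the
    covered range.  Optionally maps step onsets to the frame containing them.
    """
    ratio = frame_ms / step_ms
    spf = int(round(ratio))
    if abs(ratio - spf) > 1e-9:
        raise ParameterError("frame_ms must be an integer multiple of step_ms")
    n_units, n_steps = step_raster.shape
    n_frames = n_steps // spf
    counts = step_raster[:, :n_frames * spf].reshape(n_units, n_frames, spf).sum(axis=2)
    if onset_steps is None:
        return counts
    return counts, np.asarray(onset_steps) // spf


# ---------------------------------------------------------------------------
# calibration


def _stationary_rate(net, q, steps, burn_in, seed):
    # start from a weakly seeded state: a self-sustaining (supercritical)
    # network then reveals its plateau, while for sub/critical dynamics the
    # seeds die out during burn-in and only the driven steady state remains
    rng = np.random.default_rng(seed)
    state0 = np.where(rng.random(net.n_units) < 0.02, ACTIVE, REST
                      ).astype(np.int8)
    run = run_lattice(net, burn_in + steps, p_poiss=q, seed=seed,
                      init_state=state0)
    return run.active_counts[burn_in:].mean() / net.n_units


def rate_per_frame(active_fraction: float,
                   frame_ms: float = DEFAULT_FRAME_MS,
                   step_ms: float = DEFAULT_STEP_MS) -> float:
    """Convert per-step active fraction to spikes per unit per frame."""
    return active_fraction * frame_ms / step_ms


def closed_form_rate_sigma0(q: float) -> float:
    """Stationary active fraction of an isolated 3-state unit under drive q."""
    return q / (1.0 + 2.0 * q)


def calibrate_poisson_drive(net: LatticeNetwork, target_rate: float,
                            tol: float = 0.05, steps: int = 15000,
                            burn_in: int = 3000, n_reps: int = 3,
                            seed: int = 0, q_max: float = 0.5,
                            max_iter: int = 40) -> float:
    """Find p_poiss so the stationary spike rate matches ``target_rate``.

    ``target_rate`` is in spikes per unit per 22-ms frame.  Uses monotone
    bisection in log drive with fixed seeds per evaluation; each evaluation
    averages ``n_reps`` independent runs because stationary activity near
    criticality has large slow fluctuations.  Raises
    CalibrationInfeasibleError when the target is unreachable (self-sustained
    supercritical activity already exceeds it, or it lies above saturation).
    """
    if target_rate < 0:
        raise ParameterError("target_rate must be >= 0")
    if target_rate == 0:
        return 0.0
    target_frac = target_rate * DEFAULT_STEP_MS / DEFAULT_FRAME_MS

    def measure(q, k):
        vals = [_stationary_rate(net, q, steps, burn_in,
                                 seed=seed + 1000 + k + 131 * r)
                for r in range(n_reps)]
        return float(np.mean(vals))

    q_floor = 1e-9
    if measure(q_floor, 0) > target_frac * (1 + tol):
        raise CalibrationInfeasibleError(
            "self-sustaining activity exceeds the target at vanishing drive")
    q_lo, q_hi = q_floor, None
    q = min(max(target_frac, 1e-7), q_max)
    for k in range(12):
        r = measure(q, 1 + k)
        if r >= target_frac:
            q_hi = q
            break
        q_lo = q
        q = min(q * 10.0, q_max)
        if q_lo == q_max:
            break
    if q_hi is None:
        raise CalibrationInfeasibleError("target rate above reachable range")

    for k in range(max_iter):
        q_mid = np.sqrt(q_lo * q_hi)
        r = measure(q_mid, 100 + k)
        if abs(r - target_frac) <= tol * target_frac:
            return float(q_mid)
        if r < target_frac:
            q_lo = q_mid
        else:
            q_hi = q_mid
    return float(np.sqrt(q_lo * q_hi))


# ---------------------------------------------------------------------------
# stimulation protocol


@dataclass
class StimProtocol:
    """Repeated single-target stimulation with semi-random interleaving."""

    tc_indices: np.ndarray          # global unit indices, within the FoV
    stim_steps: int = 50            # 100 ms at 2-ms steps
    iti_steps: int = 1000           # 2 s inter-trial interval
    trials_per_tc: int = 100
    p_stim: float = 0.5             # per-step drive on the stimulated TC
    order_seed: int = 0

    def __post_init__(self):
        self.tc_indices = np.asarray(self.tc_indices, dtype=np.int64)
        if len(np.unique(self.tc_indices)) != len(self.tc_indices):
            raise ParameterError("tc_indices must be distinct")

    def schedule(self, start_step: int):
        """(units, onsets): round-interleaved trial order, non-overlapping."""
        rng = np.random.default_rng(self.order_seed)
        units = []
        for _ in range(self.trials_per_tc):
            units.extend(rng.permutation(self.tc_indices))
        units = np.asarray(units, dtype=np.int64)
        period = self.stim_steps + self.iti_steps
        onsets = start_step + period * np.arange(len(units), dtype=np.int64)
        return units, onsets


def choose_tc_indices(net: LatticeNetwork, n_tc: int = 10,
                      seed: int = 0) -> np.ndarray:
    """Pick n_tc distinct target units inside the central analysis block."""
    rng = np.random.default_rng(seed)
    fov = net.fov_indices
    return np.sort(rng.choice(fov, size=n_tc, replace=False))


def calibrate_stim_drive(net: LatticeNetwork, p_poiss: float,
                         tc_indices, target_count: float = 2.5,
                         window_frames: int = 6, stim_steps: int = 50,
                         trials_per_tc: int = 8, iti_steps: int = 200,
                         tol: float = 0.05, seed: int = 0,
                         max_iter: int = 25) -> float:
    """Bisection on p_stim so the mean TC spike count per response window
    (6 frames = 132 ms by default) matches ``target_count``."""
    tc_indices = np.asarray(tc_indices, dtype=np.int64)
    spf = int(DEFAULT_FRAME_MS / DEFAULT_STEP_MS)
    win = window_frames * spf

    def measure(p_stim, k):
        proto = StimProtocol(tc_indices, stim_steps=stim_steps,
                             iti_steps=iti_steps, trials_per_tc=trials_per_tc,
                             p_stim=p_stim, order_seed=seed)
        units, onsets = proto.schedule(start_step=1000)
        run = run_lattice(net, int(onsets[-1] + win + 10), p_poiss=p_poiss,
                          seed=seed + 7000 + k, stim_units=units,
                          stim_onsets=onsets, stim_len=stim_steps,
                          p_stim=p_stim, record_units=tc_indices)
        counts = np.zeros(len(units))
        for i, (u, o) in enumerate(zip(units, onsets)):
            ch = np.searchsorted(tc_indices, u)
            sel = (run.ev_channel == ch) & (run.ev_step >= o) & (run.ev_step < o + win)
            counts[i] = sel.sum()
        return counts.mean()

    lo, hi = 0.0, 1.0
    if measure(1.0, 0) < target_count:
        return 1.0
    for k in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = measure(mid, 1 + k)
        if abs(m - target_count) <= tol * target_count:
            return float(mid)
        if m < target_count:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


@dataclass
class ProtocolRun:
    """Step-resolution FoV spikes plus trial log from a stimulation run."""

    ev_step: np.ndarray
    ev_channel: np.ndarray        # index into fov_units
    fov_units: np.ndarray         # global unit ids exported (inner block only)
    trials: pd.DataFrame          # columns: tc_unit, onset_step
    n_steps: int
    net: LatticeNetwork
    p_poiss: float
    seed: int

    def to_recording(self, frame_ms: float = DEFAULT_FRAME_MS,
                     step_ms: float = DEFAULT_STEP_MS) -> Recording:
        ratio = frame_ms / step_ms
        spf = int(round(ratio))
        if abs(ratio - spf) > 1e-9:
            raise ParameterError("frame_ms must be an integer multiple of step_ms")
        n_frames = self.n_steps // spf
        n_cells = len(self.fov_units)
        frame = self.ev_step // spf
        keep = frame < n_frames
        counts = np.zeros((n_cells, n_frames), dtype=np.uint16)
        np.add.at(counts, (self.ev_channel[keep], frame[keep]), 1)
        pos = self.net.positions[self.fov_units]
        pos = pos - pos.min(axis=0)
        tc_cells = np.searchsorted(self.fov_units, self.trials["tc_unit"].unique())
        trials = pd.DataFrame({
            "tc": np.searchsorted(self.fov_units, self.trials["tc_unit"].to_numpy()),
            "onset_frame": self.trials["onset_step"].to_numpy() // spf,
            "onset_step": self.trials["onset_step"].to_numpy(),
        })
        meta = {"frame_ms": frame_ms, "step_ms": step_ms,
                "side": self.net.side, "spacing_um": self.net.spacing_um,
                "sigma": self.net.sigma if self.net.sigma is not None else np.nan,
                "p_poiss": self.p_poiss, "seed": self.seed,
                "source": "lattice_sim"}
        return Recording(counts=counts, positions=pos,
                         tc_indices=np.sort(tc_cells), trials=trials,
                         frame_ms=frame_ms, meta=meta)


def run_protocol(net: LatticeNetwork, protocol: StimProtocol,
                 p_poiss: float | None = None, seed: int = 0,
                 burn_in_steps: int = 2000, tail_steps: int = 400) -> ProtocolRun:
    """Run the full stimulation protocol, exporting only the inner-block units.

    The raster covers all trials plus inter-trial intervals; the trial log
    records (tc, onset step).  Only the central analysis block is exported to
    avoid boundary effects.
    """
    fov = net.fov_indices
    if not np.all(np.isin(protocol.tc_indices, fov)):
        raise ParameterError("all TC indices must lie inside the central block")
    units, onsets = protocol.schedule(start_step=burn_in_steps)
    n_steps = int(onsets[-1] + protocol.stim_steps + tail_steps) if len(onsets) \
        else burn_in_steps + tail_steps
    run = run_lattice(net, n_steps, p_poiss=p_poiss, seed=seed,
                      stim_units=units, stim_onsets=onsets,
                      stim_len=protocol.stim_steps, p_stim=protocol.p_stim,
                      record_units=fov)
    trials = pd.DataFrame({"tc_unit": units, "onset_step": onsets})
    return ProtocolRun(run.ev_step, run.ev_channel, fov, trials, n_steps, net,
                       float(net.p_poiss if p_poiss is None else p_poiss), seed)


# ---------------------------------------------------------------------------
# drive-response characterisation


@dataclass
class DriveResponseFit:
    """Log-log fit of stationary activity versus external drive."""

    drive_grid: np.ndarray
    mean_activity: np.ndarray   # stationary active fraction per drive
    gamma: float
    intercept: float
    fit_range: np.ndarray       # indices of grid points used
    dropped: np.ndarray         # grid points dropped for zero activity


def drive_response_curve(net: LatticeNetwork, drive_grid,
                         steps_per_point: int = 20000, burn_in: int = 4000,
                         seed: int = 0, fit_range=None) -> DriveResponseFit:
    """Sweep p_poiss and fit the log-log slope of stationary mean activity.

    Grid points with zero measured activity are dropped (with a warning)
    before the log transform.
    """
    drive_grid = np.asarray(drive_grid, dtype=float)
    act = np.empty(len(drive_grid))
    for i, q in enumerate(drive_grid):
        run = run_lattice(net, burn_in + steps_per_point, p_poiss=q,
                          seed=seed + 31 * i)
        act[i] = run.active_counts[burn_in:].mean() / net.n_units
    keep = act > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} drive points had zero activity; dropped")
    idx = np.flatnonzero(keep)
    if fit_range is not None:
        idx = np.intersect1d(idx, np.asarray(fit_range))
    if len(idx) < 2:
        raise ParameterError("need at least two non-zero drive points to fit")
    slope, intercept = np.polyfit(np.log(drive_grid[idx]), np.log(act[idx]), 1)
    return DriveResponseFit(drive_grid, act, float(slope), float(intercept),
                            idx, np.flatnonzero(~keep))


# ---------------------------------------------------------------------------
# critical-point location


def survival_curve(net: LatticeNetwork, sigma: float, horizon: int = 1000,
                   n_cascades: int = 1000, seed: int = 0) -> np.ndarray:
    """P(t): fraction of single-seed cascades still active at step t.

    Each cascade starts from a single active unit on a quiescent lattice with
    no external drive; the quiet state is absorbing, so survival is monotone.
    """
    net_s = set_branching(net, sigma)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, net.n_units, size=n_cascades)
    kernel_seeds = rng.integers(0, 2**31 - 1, size=n_cascades)
    alive = np.zeros(horizon)
    for u, ks in zip(seeds, kernel_seeds):
        state0 = np.zeros(net.n_units, dtype=np.int8)
        state0[u] = ACTIVE
        run = run_lattice(net_s, horizon, p_poiss=0.0, seed=int(ks),
                          init_state=state0, record_from=horizon)
        alive += run.active_counts > 0
    return alive / n_cascades


def survival_probability(net: LatticeNetwork, sigma: float, horizon: int = 500,
                         n_cascades: int = 300, seed: int = 0) -> float:
    """Fraction of single-seed cascades still active after ``horizon`` steps."""
    return float(survival_curve(net, sigma, horizon, n_cascades, seed)[-1])


#: survival exponent delta of 2+1-dimensional directed percolation:
#: at the critical point P(t) ~ t**-DP_SURVIVAL_DELTA.
DP_SURVIVAL_DELTA = 0.4505


def _survival_log_slope(P, n_cascades, t_min=10, t_max=None, min_points=8):
    """Log-log slope of the survival curve P(t) over [t_min, t_max].

    Steeper than -delta below the critical point (accelerating decay),
    shallower above it (plateau).  Returns -inf when cascades die too fast
    to leave enough resolvable points (deeply subcritical).
    """
    t = np.arange(1, len(P) + 1)
    ok = (t >= t_min) & (P * n_cascades >= 10)
    if t_max is not None:
        ok &= t <= t_max
    if ok.sum() < min_points:
        return -np.inf
    return float(np.polyfit(np.log(t[ok]), np.log(P[ok]), 1)[0])


@dataclass
class CriticalSigmaResult:
    sigma_c: float
    sigma_grid: np.ndarray
    criterion_values: np.ndarray
    criterion: str
    needs_refinement: bool = False


def find_critical_sigma(net: LatticeNetwork, sigma_grid=None,
                        criterion: str = "survival", horizon: int = 400,
                        n_cascades: int = 1500, refine_cascades: int = 6000,
                        refine_seeds: int = 2, delta: float = DP_SURVIVAL_DELTA,
                        seed: int = 0) -> CriticalSigmaResult:
    """Locate the branching parameter of the phase transition.

    Default criterion ``'survival'``: single-seed cascades decay as a power
    law P(t) ~ t**-delta exactly at the critical point (delta is the
    directed-percolation survival exponent); below it the decay is steeper,
    above it the curve flattens.  A coarse sigma grid brackets the point
    where the measured log-log decay slope crosses -delta, then the slope is
    regressed against sigma on a fine grid and solved at -delta.  The horizon
    is kept short enough that cascades stay smaller than the lattice, which
    would otherwise bias the decay through wrap-around collisions.
    Alternative ``criterion='susceptibility'``: the sigma maximising
    variance/mean of weakly driven activity.  The criterion used is recorded
    in the result.
    """
    if sigma_grid is None:
        sigma_grid = np.round(np.arange(0.95, 1.091, 0.02), 6)
    sigma_grid = np.asarray(sigma_grid, dtype=float)

    if criterion == "susceptibility":
        chi = np.empty(len(sigma_grid))
        for i, s in enumerate(sigma_grid):
            net_s = set_branching(net, s)
            run = run_lattice(net_s, 8000, p_poiss=1e-5, seed=seed + i)
            c = run.active_counts[2000:]
            chi[i] = c.var() / max(c.mean(), 1e-12)
        i = int(np.argmax(chi))
        return CriticalSigmaResult(float(sigma_grid[i]), sigma_grid, chi,
                                   "susceptibility",
                                   needs_refinement=i in (0, len(sigma_grid) - 1))

    def decay_slope(s, k, n):
        P = survival_curve(net, s, horizon, n, seed=seed + 101 * k)
        return _survival_log_slope(P, n, t_max=horizon)

    coarse = np.array([decay_slope(s, i, n_cascades)
                       for i, s in enumerate(sigma_grid)])
    above = coarse > -delta  # shallower than critical decay
    cross = np.flatnonzero(~above[:-1] & above[1:])
    if len(cross) == 0:
        i = int(np.argmin(np.abs(coarse + delta)))
        return CriticalSigmaResult(float(sigma_grid[i]), sigma_grid, coarse,
                                   "survival", needs_refinement=True)
    def regress(fine, n_per, key):
        xs, ys = [], []
        for j, s in enumerate(fine):
            for r in range(refine_seeds):
                v = decay_slope(s, key + 10 * j + r, n_per)
                if np.isfinite(v):
                    xs.append(s)
                    ys.append(v)
        b, a = np.polyfit(xs, ys, 1)  # slope(sigma) ~ a + b*sigma
        return float(np.clip((-delta - a) / b, fine[0], fine[-1])), np.asarray(ys)

    i = int(cross[-1])
    half = 0.75 * (sigma_grid[i + 1] - sigma_grid[i])
    centre = 0.5 * (sigma_grid[i] + sigma_grid[i + 1])
    fine1 = np.linspace(centre - half, centre + half, 5)
    s0, _ = regress(fine1, refine_cascades, 1000)
    fine2 = np.linspace(s0 - 0.004, s0 + 0.004, 5)
    s_c, ys = regress(fine2, 2 * refine_cascades, 5000)
    return CriticalSigmaResult(s_c, fine2, ys, "survival")


# ---------------------------------------------------------------------------
# output strength


def output_strength(net: LatticeNetwork, max_order: int = 5) -> np.ndarray:
    """Structural spike yield OS(i) = sum_{o=1..max_order} sum_j (p_trans A)^o_ij.

    Estimates the expected number of spikes a single spike of unit i generates
    through directed paths of length <= max_order, ignoring dynamics.
    """
    a = net.adjacency.astype(np.float64)
    n = a.shape[0]
    acc = np.zeros(n)
    u = np.ones(n)
    for _ in range(max_order):
        u = net.p_trans * (a @ u)
        acc += u
    return acc
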