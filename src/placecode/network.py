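"""Feedforward E/I spiking network on a 2-D grid.

Adaptive exponential integrate-and-fire (AdEx) neurons tile a square grid,
75% excitatory and 25% inhibitory (one I cell per 2x2 block).  Both
populations can receive an external excitatory drive whose mean presynaptic
count falls off as a spatial Gaussian; E cells additionally receive
feedforward inhibition from I cells, connected with a Gaussian
distance-dependent Bernoulli probability.  All other connection classes
(E->E, E->I recurrent, I->I) are absent.

Units: capacitance pF, conductance nS, voltage mV, time ms, current pA
(nS * mV = pA, pA / pF = mV / ms).

Two read-outs are extracted per trial:

* the *synaptic field*: E cells whose net synaptic current at threshold,
  ``i_net = g_exc (V_T - E_exc) + g_inh (V_T - E_inh)``, dips below (is more
  negative than) rheobase at any point in the stimulus window;
* the *activated area*: E cells that fired at least one spike.

Masks are measured by the diameter of the minimal enclosing circle of the
cell centers and by the length of the projection onto the tonotopic (x)
axis, both in cell units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import predictions as pred
from .predictions import PredictionCurve


class ConfigError(ValueError):
    pass


class IntegrationError(RuntimeError):
    """Network state became non-finite during integration."""


class EstimationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdExParams:
    """Adaptive exponential integrate-and-fire parameters."""

    C: float        # membrane capacitance, pF
    g_L: float      # leak conductance, nS
    E_L: float      # resting potential, mV
    V_T: float      # spike-initiation threshold, mV
    delta_T: float  # slope factor, mV
    a: float        # subthreshold adaptation, nS
    b: float        # spike-triggered adaptation increment, pA
    tau_w: float    # adaptation time constant, ms
    V_reset: float  # post-spike reset, mV
    V_peak: float   # spike detection voltage, mV


#: Regular-spiking pyramidal defaults.  g_L * (V_T - E_L - delta_T) = 270 pA,
#: i.e. a rheobase magnitude of 0.27 nA for the E population.
RS_PYRAMIDAL = AdExParams(C=150.0, g_L=15.0, E_L=-70.0, V_T=-50.0, delta_T=2.0,
                          a=2.0, b=60.0, tau_w=150.0, V_reset=-58.0, V_peak=-30.0)

#: Fast-spiking interneuron defaults: lower rheobase than the E cells but
#: integrating slowly enough that feedforward inhibition lags the excitatory
#: drive by roughly ten milliseconds; spike-triggered adaptation keeps each
#: cell to a handful of spikes per brief stimulus.
FS_INTERNEURON = AdExParams(C=100.0, g_L=10.0, E_L=-65.0, V_T=-50.0, delta_T=1.0,
                            a=0.0, b=150.0, tau_w=60.0, V_reset=-60.0, V_peak=-30.0)


@dataclass(frozen=True)
class SynapseParams:
    q_exc: float = 0.2      # unitary drive conductance, nS per event
    q_inh: float = 1.0      # unitary I->E conductance, nS per spike
    tau_exc: float = 15.0   # ms
    tau_inh: float = 8.0    # ms
    E_exc: float = 0.0      # mV
    E_inh: float = -80.0    # mV
    delay_ms: float = 1.5   # synaptic transmission delay


@dataclass(frozen=True)
class NetworkConfig:
    grid: int = 100               # side length in cells (full scale: 200)
    e_fraction: float = 0.75
    i_fraction: float = 0.25
    pitch_um: float = 7.5         # inter-cell distance
    conn_sigma_um: float = 75.0   # I->E probability spread
    conn_peak: float = 0.4
    adex_e: AdExParams = RS_PYRAMIDAL
    adex_i: AdExParams = FS_INTERNEURON
    syn: SynapseParams = SynapseParams()
    dt_ms: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid < 4 or self.grid % 2 != 0:
            raise ConfigError(f"grid must be even and >= 4, got {self.grid}")
        if abs(self.e_fraction + self.i_fraction - 1.0) > 1e-12:
            raise ConfigError("e_fraction + i_fraction must equal 1")
        if abs(self.i_fraction - 0.25) > 1e-12:
            raise ConfigError("the 2x2 E/I tiling requires i_fraction == 0.25")
        if self.dt_ms > 0.1:
            raise ConfigError("dt must be <= 0.1 ms")


@dataclass(frozen=True)
class StimulusConfig:
    """Gaussian synaptic barrage delivered to one population."""

    center: tuple[float, float]   # (x, y) in cells
    sigma_cells: float            # spatial spread of the drive
    peak_inputs: float            # mean presynaptic count at the center
    duration_ms: float = 50.0
    trial_sd_frac: float = 0.25   # per-trial count randomization
    target: Literal["E", "I"] = "E"
    event_mode: Literal["single", "poisson"] = "single"
    rate_hz: float = 20.0         # per-source rate in poisson mode

    def mean_inputs(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        d2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2
        return self.peak_inputs * np.exp(-d2 / (2.0 * self.sigma_cells ** 2))


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

class Network:
    """Built network: positions, E/I assignment and I->E adjacency."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        g = cfg.grid
        xs, ys = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        is_i = (xs % 2 == 1) & (ys % 2 == 1)   # 1 I per 2x2 block -> exact 25%
        self.e_x = xs[~is_i].astype(np.int32)
        self.e_y = ys[~is_i].astype(np.int32)
        self.i_x = xs[is_i].astype(np.int32)
        self.i_y = ys[is_i].astype(np.int32)
        self.n_e = self.e_x.size
        self.n_i = self.i_x.size
        self._build_connectivity()

    def _build_connectivity(self) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        sigma_cells = cfg.conn_sigma_um / cfg.pitch_um
        cutoff = 4.0 * sigma_cells
        g = cfg.grid
        # E-index lookup per grid cell (-1 where an I cell sits)
        e_id = np.full((g, g), -1, dtype=np.int64)
        e_id[self.e_x, self.e_y] = np.arange(self.n_e)
        indptr = np.zeros(self.n_i + 1, dtype=np.int64)
        chunks: list[np.ndarray] = []
        r = int(math.ceil(cutoff))
        for k in range(self.n_i):
            ix, iy = int(self.i_x[k]), int(self.i_y[k])
            x0, x1 = max(0, ix - r), min(g, ix + r + 1)
            y0, y1 = max(0, iy - r), min(g, iy + r + 1)
            sub = e_id[x0:x1, y0:y1]
            wx, wy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1), indexing="ij")
            d2_um = ((wx - ix) ** 2 + (wy - iy) ** 2) * cfg.pitch_um ** 2
            p = cfg.conn_peak * np.exp(-d2_um / (2.0 * cfg.conn_sigma_um ** 2))
            hit = (sub >= 0) & (rng.random(p.shape) < p)
            targets = sub[hit].astype(np.int64)
            chunks.append(targets)
            indptr[k + 1] = indptr[k] + targets.size
        self.conn_indptr = indptr
        self.conn_targets = (np.concatenate(chunks) if chunks
                             else np.empty(0, dtype=np.int64))

    def out_degree(self, i_cell: int) -> int:
        return int(self.conn_indptr[i_cell + 1] - self.conn_indptr[i_cell])

    def targets_of(self, i_cell: int) -> np.ndarray:
        return self.conn_targets[self.conn_indptr[i_cell]:self.conn_indptr[i_cell + 1]]

    def expected_out_degree(self, i_cell: int) -> float:
        """Sum of connection probabilities over all E cells (exact mean)."""
        cfg = self.cfg
        ix, iy = float(self.i_x[i_cell]), float(self.i_y[i_cell])
        d2_um = ((self.e_x - ix) ** 2 + (self.e_y - iy) ** 2) * cfg.pitch_um ** 2
        return float(np.sum(cfg.conn_peak * np.exp(-d2_um / (2 * cfg.conn_sigma_um ** 2))))


def build_network(cfg: NetworkConfig) -> Network:
    """Deterministic (seeded) construction of the E/I grid and I->E edges."""
    return Network(cfg)


# --------------------------------------------------------------------------
# external drive
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Drive:
    """Realized synaptic barrage: one row per event."""

    target: str                 # "E" or "I"
    cell_idx: np.ndarray        # population index per event
    times_ms: np.ndarray        # event time per event
    duration_ms: float


def generate_drive(stim: StimulusConfig, net: Network,
                   rng: np.random.Generator) -> Drive:
    """Draw per-cell event counts and uniform event times for one trial.

    Counts are Gaussian around the spatial mean with sd
    ``trial_sd_frac * mean``, truncated at zero and rounded; each presynaptic
    source contributes a single event at a uniform time in the stimulus
    window (or a Poisson train in ``poisson`` mode).
    """
    if stim.target == "E":
        x, y = net.e_x, net.e_y
    elif stim.target == "I":
        x, y = net.i_x, net.i_y
    else:
        raise ConfigError(f"unknown drive target {stim.target!r}")
    mean = stim.mean_inputs(x.astype(float), y.astype(float))
    noisy = rng.normal(mean, stim.trial_sd_frac * mean)
    counts = np.rint(np.maximum(noisy, 0.0)).astype(np.int64)
    if stim.event_mode == "poisson":
        lam = counts * stim.rate_hz * stim.duration_ms / 1000.0
        counts = rng.poisson(lam)
    total = int(counts.sum())
    cell_idx = np.repeat(np.arange(counts.size), counts)
    times = rng.uniform(0.0, stim.duration_ms, size=total)
    return Drive(target=stim.target, cell_idx=cell_idx, times_ms=times,
                 duration_ms=stim.duration_ms)


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class TrialResult:
    """Outcome of one simulated sweep."""

    duration_ms: float
    dt_ms: float
    e_spike_counts: np.ndarray          # spikes per E cell
    i_spike_counts: np.ndarray
    e_spike_times: tuple[np.ndarray, np.ndarray]   # (cell index, time ms)
    i_spike_times: tuple[np.ndarray, np.ndarray]
    i_net_min: np.ndarray               # most negative i_net per E cell (pA)
    i_net_mean: np.ndarray = None       # stimulus-window mean per E cell (pA)
    trace_times: Optional[np.ndarray] = None
    g_exc_t: Optional[np.ndarray] = None   # (n_samples, n_e), nS
    g_inh_t: Optional[np.ndarray] = None
    i_net_t: Optional[np.ndarray] = None   # (n_samples, n_e), pA


def simulate_trial(net: Network, drives: Sequence[Drive],
                   duration_ms: Optional[float] = None,
                   tail_ms: float = 10.0,
                   record_traces: bool = False,
                   trace_stride: int = 10) -> TrialResult:
    """Integrate one trial with forward Euler at ``cfg.dt_ms``.

    ``i_net`` is tracked at the E-cell threshold V_T over the stimulus
    window; a ``tail_ms`` margin lets delayed spikes play out.  Raises
    :class:`IntegrationError` if the state becomes non-finite.
    """
    cfg = net.cfg
    syn = cfg.syn
    dt = cfg.dt_ms
    stim_dur = duration_ms if duration_ms is not None else max(
        (d.duration_ms for d in drives), default=50.0)
    n_steps = int(math.ceil((stim_dur + tail_ms) / dt))
    stim_steps = int(math.ceil(stim_dur / dt))

    # per-step drive conductance increments
    inc_e = np.zeros((n_steps, net.n_e), dtype=np.float64)
    inc_i = np.zeros((n_steps, net.n_i), dtype=np.float64)
    for d in drives:
        steps = np.minimum((d.times_ms / dt).astype(np.int64), n_steps - 1)
        buf = inc_e if d.target == "E" else inc_i
        np.add.at(buf, (steps, d.cell_idx), syn.q_exc)

    pe, pi = cfg.adex_e, cfg.adex_i
    V_e = np.full(net.n_e, pe.E_L)
    w_e = np.zeros(net.n_e)
    V_i = np.full(net.n_i, pi.E_L)
    w_i = np.zeros(net.n_i)
    gE_e = np.zeros(net.n_e)   # drive conductance onto E
    gI_e = np.zeros(net.n_e)   # feedforward inhibition onto E
    gE_i = np.zeros(net.n_i)   # drive conductance onto I

    decay_e = math.exp(-dt / syn.tau_exc)
    decay_i = math.exp(-dt / syn.tau_inh)
    delay_steps = max(1, int(round(syn.delay_ms / dt)))
    inh_ring = np.zeros((delay_steps, net.n_e))

    i_net_min = np.zeros(net.n_e)
    i_net_sum = np.zeros(net.n_e)
    e_counts = np.zeros(net.n_e, dtype=np.int64)
    i_counts = np.zeros(net.n_i, dtype=np.int64)
    e_sp_cells: list[np.ndarray] = []
    e_sp_times: list[float] = []
    i_sp_cells: list[np.ndarray] = []
    i_sp_times: list[float] = []

    if record_traces:
        n_samples = n_steps // trace_stride + 1
        trace_times = np.empty(n_samples)
        g_exc_t = np.empty((n_samples, net.n_e))
        g_inh_t = np.empty((n_samples, net.n_e))
        sample = 0

    drive_force_e = pe.V_T - syn.E_exc   # mV; negative -> inward current
    drive_force_i = pe.V_T - syn.E_inh

    for t in range(n_steps):
        slot = t % delay_steps
        gI_e += inh_ring[slot]
        inh_ring[slot] = 0.0
        gE_e += inc_e[t]
        gE_i += inc_i[t]

        if t < stim_steps:
            i_net = gE_e * drive_force_e + gI_e * drive_force_i
            np.minimum(i_net_min, i_net, out=i_net_min)
            i_net_sum += i_net

        if record_traces and t % trace_stride == 0:
            trace_times[sample] = t * dt
            g_exc_t[sample] = gE_e
            g_inh_t[sample] = gI_e
            sample += 1

        # E population
        exp_e = pe.g_L * pe.delta_T * np.exp(
            np.minimum((V_e - pe.V_T) / pe.delta_T, 20.0))
        I_syn_e = gE_e * (syn.E_exc - V_e) + gI_e * (syn.E_inh - V_e)
        dV = (-pe.g_L * (V_e - pe.E_L) + exp_e - w_e + I_syn_e) * (dt / pe.C)
        dw = (pe.a * (V_e - pe.E_L) - w_e) * (dt / pe.tau_w)
        V_e += dV
        w_e += dw
        sp = V_e >= pe.V_peak
        if sp.any():
            idx = np.nonzero(sp)[0]
            V_e[idx] = pe.V_reset
            w_e[idx] += pe.b
            e_counts[idx] += 1
            e_sp_cells.append(idx)
            e_sp_times.append(t * dt)

        # I population
        exp_i = pi.g_L * pi.delta_T * np.exp(
            np.minimum((V_i - pi.V_T) / pi.delta_T, 20.0))
        I_syn_i = gE_i * (syn.E_exc - V_i)
        dVi = (-pi.g_L * (V_i - pi.E_L) + exp_i - w_i + I_syn_i) * (dt / pi.C)
        dwi = (pi.a * (V_i - pi.E_L) - w_i) * (dt / pi.tau_w)
        V_i += dVi
        w_i += dwi
        spi = V_i >= pi.V_peak
        if spi.any():
            idx = np.nonzero(spi)[0]
            V_i[idx] = pi.V_reset
            w_i[idx] += pi.b
            i_counts[idx] += 1
            i_sp_cells.append(idx)
            i_sp_times.append(t * dt)
            # schedule feedforward IPSGs after the transmission delay
            arrive = (t + delay_steps) % delay_steps
            for k in idx:
                tg = net.targets_of(int(k))
                np.add.at(inh_ring[arrive], tg, syn.q_inh)

        gE_e *= decay_e
        gE_i *= decay_e
        gI_e *= decay_i

        if not np.isfinite(V_e).all() or not np.isfinite(V_i).all():
            raise IntegrationError(f"non-finite membrane state at t={t * dt} ms")

    def _pack(cells: list[np.ndarray], times: list[float]) -> tuple[np.ndarray, np.ndarray]:
        if not cells:
            return (np.empty(0, dtype=np.int64), np.empty(0))
        c = np.concatenate(cells)
        tt = np.concatenate([np.full(a.size, tv) for a, tv in zip(cells, times)])
        return (c, tt)

    result = TrialResult(
        duration_ms=stim_dur, dt_ms=dt,
        e_spike_counts=e_counts, i_spike_counts=i_counts,
        e_spike_times=_pack(e_sp_cells, e_sp_times),
        i_spike_times=_pack(i_sp_cells, i_sp_times),
        i_net_min=i_net_min,
        i_net_mean=i_net_sum / stim_steps,
    )
    if record_traces:
        result.trace_times = trace_times[:sample]
        result.g_exc_t = g_exc_t[:sample]
        result.g_inh_t = g_inh_t[:sample]
        result.i_net_t = (result.g_exc_t * drive_force_e
                          + result.g_inh_t * drive_force_i)
    return result


# --------------------------------------------------------------------------
# rheobase
# --------------------------------------------------------------------------

def analytic_rheobase(p: AdExParams) -> float:
    """Closed-form AdEx rheobase magnitude (pA) for a = 0."""
    return p.g_L * (p.V_T - p.E_L - p.delta_T)


def fires_with_current(p: AdExParams, current_pa: float, dt: float = 0.02,
                       t_max: float = 1000.0) -> bool:
    """Whether a single AdEx neuron fires under a constant injected current."""
    V, w = p.E_L, 0.0
    n = int(t_max / dt)
    for _ in range(n):
        arg = (V - p.V_T) / p.delta_T
        exp_term = p.g_L * p.delta_T * math.exp(min(arg, 20.0))
        V += (-p.g_L * (V - p.E_L) + exp_term - w + current_pa) * dt / p.C
        w += (p.a * (V - p.E_L) - w) * dt / p.tau_w
        if V >= p.V_peak:
            return True
    return False


def estimate_rheobase(p: AdExParams, dt: float = 0.02, t_max: float = 1000.0,
                      rel_tol: float = 1e-3, max_iter: int = 60) -> float:
    """Bisect the constant-current spike threshold; returns magnitude in pA.

    The synaptic-field criterion uses the negative (inward) of this value.
    """
    hi = 2.0 * max(analytic_rheobase(p), 1.0)
    for _ in range(10):
        if fires_with_current(p, hi, dt, t_max):
            break
        hi *= 2.0
    else:
        raise EstimationError("could not bracket rheobase from above")
    lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if fires_with_current(p, mid, dt, t_max):
            hi = mid
        else:
            lo = mid
        if (hi - lo) <= rel_tol * hi:
            return hi
    raise EstimationError("rheobase bisection did not converge")


# --------------------------------------------------------------------------
# masks and measurements
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldMask:
    kind: Literal["synaptic_field", "activated_area"]
    cells: np.ndarray   # boolean over E-population indices

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", np.asarray(self.cells, dtype=bool))

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


@dataclass(frozen=True)
class Measurement:
    diameter_cells: float
    projection_cells: int
    empty: bool = False


def compute_synaptic_field(trial: TrialResult, i_rh: float,
                           reduce: Literal["min", "mean"] = "min") -> FieldMask:
    """E cells whose net synaptic current reached rheobase (``i_rh`` < 0 pA).

    ``reduce`` selects how i_net is aggregated over the stimulus window:
    ``"min"`` takes its extremum (most negative instant), ``"mean"`` its
    window average.  The extremum is blind to feedforward inhibition, which
    arrives ~10 ms after the drive by construction, so the experiment
    protocols aggregate by the mean; the extremum remains the per-instant
    inclusion rule.  Inclusion is boundary-inclusive: a cell exactly at
    rheobase is in the field.  Purely inhibitory input keeps i_net positive
    at V_T (V_T > E_inh) and can never add a cell.
    """
    if i_rh >= 0:
        raise ValueError("i_rh must be the negative (inward) rheobase current")
    stat = trial.i_net_min if reduce == "min" else trial.i_net_mean
    return FieldMask("synaptic_field", stat <= i_rh)


def compute_activated_area(trial: TrialResult) -> FieldMask:
    """E cells that fired at least one action potential."""
    return FieldMask("activated_area", trial.e_spike_counts >= 1)


def combine_masks(masks: Sequence[FieldMask], min_frac: float = 0.5) -> FieldMask:
    """Sweep-averaged mask: cells included in >= ``min_frac`` of sweeps."""
    if not masks:
        raise ValueError("need at least one mask")
    freq = np.mean([m.cells for m in masks], axis=0)
    return FieldMask(masks[0].kind, freq >= min_frac)


def union_masks(masks: Sequence[FieldMask]) -> FieldMask:
    out = np.zeros_like(masks[0].cells, dtype=bool)
    for m in masks:
        out |= m.cells
    return FieldMask(masks[0].kind, out)


def _min_enclosing_circle(points: np.ndarray) -> float:
    """Diameter of the minimal enclosing circle (Welzl, on hull points)."""
    pts = np.unique(points, axis=0).astype(float)
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 3:
        try:
            from scipy.spatial import ConvexHull
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (collinear) input: Welzl handles it directly
    rng = np.random.default_rng(0)
    order = rng.permutation(pts.shape[0])
    pts = pts[order]

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, float(np.hypot(*(a - c)))

    def circle_three(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            # collinear: fall back to the widest pair
            best = None
            for p, q in ((a, b), (a, c), (b, c)):
                cc, r = circle_two(p, q)
                if best is None or r > best[1]:
                    best = (cc, r)
            return best
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        center = np.array([ux, uy])
        return center, float(np.hypot(*(a - center)))

    def inside(center, r, p):
        return np.hypot(*(p - center)) <= r + 1e-9

    center, r = circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if inside(center, r, pts[i]):
            continue
        center, r = circle_two(pts[i], pts[0])
        for j in range(1, i):
            if inside(center, r, pts[j]):
                continue
            center, r = circle_two(pts[i], pts[j])
            for k in range(j):
                if inside(center, r, pts[k]):
                    continue
                center, r = circle_three(pts[i], pts[j], pts[k])
    return 2.0 * r


def measure(mask: FieldMask, net: Network) -> Measurement:
    """Diameter (minimal enclosing circle) and tonotopic projection length.

    Both in cell units; an empty mask reports diameter 0 with the ``empty``
    flag set.
    """
    sel = mask.cells
    if not sel.any():
        return Measurement(diameter_cells=0.0, projection_cells=0, empty=True)
    xs = net.e_x[sel]
    ys = net.e_y[sel]
    projection = int(np.unique(xs).size)
    diameter = _min_enclosing_circle(np.column_stack([xs, ys]))
    return Measurement(diameter_cells=diameter, projection_cells=projection)


# --------------------------------------------------------------------------
# experiment protocols
# --------------------------------------------------------------------------

PROTOCOLS = (
    "addition_colocated",
    "addition_separated",
    "multiplication_colocated",
    "multiplication_shifted",
    "two_exc_one_inh",
    "center_surround",
)


def _default_sweep(protocol: str) -> list[float]:
    return {
        "addition_colocated": [2, 6, 10, 13, 16, 19, 22],
        "addition_separated": [0, 5, 10, 15, 20, 25, 30, 36],
        "multiplication_colocated": [2, 4, 6, 8, 10, 13, 16, 20],
        "multiplication_shifted": [0, 4, 8, 12, 16, 20, 26, 32],
        "two_exc_one_inh": [0, 4, 8, 12, 16, 20, 25, 30],
        "center_surround": [0, 6, 10, 14, 18, 24, 30, 38],
    }[protocol]


@dataclass(frozen=True)
class _TrialPlan:
    """Trials to run for one swept value and how to combine them."""

    trials: tuple[tuple[StimulusConfig, ...], ...]
    combine: Literal["single", "sum_lengths", "union_masks"]


def _plan(protocol: str, value: float, params: dict, center: tuple[float, float],
          variant: str) -> _TrialPlan:
    cx, cy = center
    peak_exc = params.get("peak_exc", 400.0)
    # center-surround needs stronger surrounds for the flanks to carve the
    # neighbouring composite's excitatory field
    peak_inh = params.get("peak_inh",
                          250.0 if protocol == "center_surround" else 150.0)
    dur = params.get("duration_ms", 50.0)

    def E(x, sigma):
        return StimulusConfig(center=(x, cy), sigma_cells=sigma, peak_inputs=peak_exc,
                              duration_ms=dur, target="E")

    def I(x, sigma):
        return StimulusConfig(center=(x, cy), sigma_cells=sigma, peak_inputs=peak_inh,
                              duration_ms=dur, target="I")

    if protocol == "addition_colocated":
        sb = params.get("sigma_beta", 10.0)
        return _TrialPlan(((E(cx, value), E(cx, sb)),), "single")
    if protocol == "addition_separated":
        s = params.get("sigma", 5.0)
        return _TrialPlan(((E(cx - value / 2, s), E(cx + value / 2, s)),), "single")
    if protocol == "multiplication_colocated":
        se = params.get("sigma_exc", 10.0)
        return _TrialPlan(((E(cx, se), I(cx, value)),), "single")
    if protocol == "multiplication_shifted":
        se = params.get("sigma_exc", 8.0)
        si = params.get("sigma_inh", 8.0)
        return _TrialPlan(((E(cx + value, se), I(cx, si)),), "single")
    if protocol == "two_exc_one_inh":
        s = params.get("sigma", 5.0)
        e1, e2, inh = E(cx - value, s), E(cx + value, s), I(cx, s)
        if variant == "sequential":
            return _TrialPlan(((e1, inh), (e2, inh)), "sum_lengths")
        return _TrialPlan(((e1, e2, inh),), "single")
    if protocol == "center_surround":
        se = params.get("sigma_exc", 5.0)
        si = params.get("sigma_inh", 8.5)
        c1, c2 = cx - value / 2, cx + value / 2
        if variant == "sequential":
            return _TrialPlan(((E(c1, se), I(c1, si)), (E(c2, se), I(c2, si))),
                              "union_masks")
        return _TrialPlan(((E(c1, se), I(c1, si), E(c2, se), I(c2, si)),), "single")
    raise ConfigError(f"unknown protocol {protocol!r}")


def run_experiment(protocol: str, params: Optional[dict] = None,
                   n_sweeps: int = 10, seed: int = 0,
                   net_cfg: Optional[NetworkConfig] = None,
                   variant: str = "simultaneous",
                   sweep: Optional[Iterable[float]] = None,
                   i_rh: Optional[float] = None,
                   net: Optional[Network] = None,
                   field_reduce: Literal["min", "mean"] = "mean") -> pd.DataFrame:
    """Run a stimulus-sweep protocol; one row per swept value.

    Columns: protocol, variant, param, and mean/sd over sweeps of the
    synaptic-field and activated-area diameter and projection.  Sequential
    variants deliver each input in its own trial and combine the single-input
    results (scalar length sum for the shared-inhibitor protocol, mask union
    for center-surround).
    """
    if protocol not in PROTOCOLS:
        raise ConfigError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
    params = dict(params or {})
    cfg = net_cfg or NetworkConfig(seed=seed)
    if net is None:
        net = build_network(cfg)
    if i_rh is None:
        i_rh = -estimate_rheobase(cfg.adex_e)
    center = params.get("center", (cfg.grid / 2.0, cfg.grid / 2.0))
    values = list(sweep) if sweep is not None else _default_sweep(protocol)
    rng = np.random.default_rng(seed + 1)

    rows = []
    for value in values:
        plan = _plan(protocol, value, params, center, variant)
        f_d, f_p, a_d, a_p = [], [], [], []
        for _ in range(n_sweeps):
            field_masks, area_masks = [], []
            for stim_group in plan.trials:
                drives = [generate_drive(s, net, rng) for s in stim_group]
                trial = simulate_trial(net, drives)
                field_masks.append(compute_synaptic_field(trial, i_rh, field_reduce))
                area_masks.append(compute_activated_area(trial))
            if plan.combine == "sum_lengths":
                fm = [measure(m, net) for m in field_masks]
                am = [measure(m, net) for m in area_masks]
                f_d.append(sum(m.diameter_cells for m in fm))
                f_p.append(sum(m.projection_cells for m in fm))
                a_d.append(sum(m.diameter_cells for m in am))
                a_p.append(sum(m.projection_cells for m in am))
            else:
                if plan.combine == "union_masks":
                    field_masks = [union_masks(field_masks)]
                    area_masks = [union_masks(area_masks)]
                fm = measure(field_masks[0], net)
                am = measure(area_masks[0], net)
                f_d.append(fm.diameter_cells)
                f_p.append(fm.projection_cells)
                a_d.append(am.diameter_cells)
                a_p.append(am.projection_cells)
        rows.append({
            "protocol": protocol, "variant": variant, "param": value,
            "n_sweeps": n_sweeps,
            "field_diameter_mean": float(np.mean(f_d)),
            "field_diameter_sd": float(np.std(f_d, ddof=1)) if n_sweeps > 1 else 0.0,
            "field_projection_mean": float(np.mean(f_p)),
            "field_projection_sd": float(np.std(f_p, ddof=1)) if n_sweeps > 1 else 0.0,
            "area_diameter_mean": float(np.mean(a_d)),
            "area_diameter_sd": float(np.std(a_d, ddof=1)) if n_sweeps > 1 else 0.0,
            "area_projection_mean": float(np.mean(a_p)),
            "area_projection_sd": float(np.std(a_p, ddof=1)) if n_sweeps > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def matched_prediction(protocol: str, values: Sequence[float], unit_len: float,
                       params: Optional[dict] = None,
                       variant: str = "simultaneous") -> PredictionCurve:
    """Algebraic prediction evaluated at the simulator's swept parameters.

    ``unit_len`` converts a drive width sigma (cells) into an equivalent
    interval length (cells of field extent per sigma cell); separations are
    already in cells and pass through unchanged.  Intended for rank (shape)
    comparison against simulated mean curves.
    """
    params = dict(params or {})

    def L(sigma: float) -> int:
        return max(1, int(round(unit_len * sigma)))

    vals_i = [int(round(v)) for v in values]
    if protocol == "addition_colocated":
        lengths = sorted({L(v) for v in values})
        curve = pred.addition_same_start(L(params.get("sigma_beta", 10.0)), lengths)
        lut = dict(curve.points)
        pts = tuple(zip(vals_i, [lut[L(v)] for v in values]))
        return PredictionCurve("addition_same_start", "sigma_cells", pts)
    if protocol == "addition_separated":
        return pred.addition_shifted(L(params.get("sigma", 5.0)), vals_i)
    if protocol == "multiplication_colocated":
        lengths = sorted({L(v) for v in values})
        curve = pred.multiplication_same_start(L(params.get("sigma_exc", 10.0)), lengths)
        lut = dict(curve.points)
        pts = tuple(zip(vals_i, [lut[L(v)] for v in values]))
        return PredictionCurve("multiplication_same_start", "sigma_cells", pts)
    if protocol == "multiplication_shifted":
        return pred.multiplication_shifted(L(params.get("sigma_exc", 8.0)),
                                           L(params.get("sigma_inh", 8.0)), vals_i)
    if protocol == "two_exc_one_inh":
        return pred.two_exc_one_inh(L(params.get("sigma", 5.0)),
                                    L(params.get("sigma", 5.0)), vals_i)
    if protocol == "center_surround":
        mode = "sequential" if variant == "sequential" else "simultaneous"
        se = params.get("sigma_exc", 5.0)
        si = params.get("sigma_inh", 8.5)
        # the co-centred, wider inhibitory drive acts as an annulus around
        # the excitatory field: flank width ~ half the extent difference
        flank = max(1, int(round(unit_len * (si - se) / 2)))
        return pred.center_surround(L(se), flank, vals_i, mode)
    raise ConfigError(f"unknown protocol {protocol!r}")
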