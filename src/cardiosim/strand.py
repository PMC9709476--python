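"""Monodomain 1D cable solver.

Tissue is a linear syncytium of coupled myocytes:

    dVm/dt = D * d2Vm/dx2 - I_ion / Cm

with a scalar diffusion coefficient D (mm²/ms) that sets the conduction
velocity, second-order central differences for the diffusion term, no-flux
(mirror) boundaries, and forward Euler in time (membrane kinetics advance
with the same operator-split scheme as the single cell).

The default transmural strand is 15 mm long, 100 nodes at dx = 0.15 mm,
with a 25:35:40 ENDO:MID:EPI layout, paced from the ENDO end, and
D = 0.127 mm²/ms, which yields a planar conduction velocity near 70 cm/s.
Homogeneous strands with a centered block of "affected" nodes (carrying
their own conductance-factor set) support source–sink / critical-mass
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import ord
from .ord import CellType, CellParams, N_STATE, NumericalBlowup
from .pharmacology import ConductanceFactors

__all__ = [
    "StrandConfig", "StrandTrace", "build_transmural_strand",
    "build_homogeneous_strand", "simulate_strand", "measure_cv",
    "ConductionBlock",
]


class ConductionBlock(RuntimeError):
    """No activation detected at a measurement site."""


@dataclass
class StrandConfig:
    """Geometry, layout, pacing and numerics of a 1D strand run."""

    n_nodes: int = 100
    dx: float = 0.15                  # mm
    D: float = 0.127                  # mm²/ms
    layout: np.ndarray = None         # per-node CellType codes
    node_factors: np.ndarray = None   # (n_nodes, 9) multiplicative factors
    pacing_nodes: int = 3             # stimulus applied to the first k nodes
    bcl: float = 1000.0               # ms
    n_beats: int = 5
    dt: float = 0.005                 # ms
    stim_amplitude: float = -80.0     # µA/µF
    stim_duration: float = 1.0        # ms (tissue capture needs > the
    # single-cell 0.5 ms against the diffusive load)
    cell_prebeats: int = 100          # single-cell steady-state pre-pacing
    extra_stims: list = field(default_factory=list)
    # each: (t0_ms, duration_ms, amplitude, node_lo, node_hi)
    rec_dt: float = 0.1               # ms, trace sampling interval
    model: str = "ord"                # "ord" | "surrogate"
    surrogate_params: object = None

    def __post_init__(self):
        if self.layout is None:
            self.layout = np.full(self.n_nodes, int(CellType.ENDO))
        self.layout = np.asarray(self.layout, dtype=np.int64)
        if self.node_factors is None:
            self.node_factors = np.ones((self.n_nodes, len(ord.CHANNELS)))
        self.node_factors = np.asarray(self.node_factors, dtype=float)
        if self.layout.shape != (self.n_nodes,):
            raise ValueError("layout must cover all nodes")
        if self.node_factors.shape != (self.n_nodes, len(ord.CHANNELS)):
            raise ValueError("node_factors must be (n_nodes, 9)")
        if self.D < 0:
            raise ValueError("D must be >= 0")

    @property
    def length(self) -> float:
        return self.n_nodes * self.dx

    @property
    def x(self) -> np.ndarray:
        """Node centers (mm)."""
        return (np.arange(self.n_nodes) + 0.5) * self.dx


@dataclass
class StrandTrace:
    """Space × time membrane-potential record of one strand run."""

    t: np.ndarray           # ms
    vm: np.ndarray          # (n_nodes, n_time) mV
    x: np.ndarray           # mm
    stim_times: np.ndarray  # onsets of the pacing stimuli (ms)
    stim_log: list          # all stimulus events (t0, dur, amp, lo, hi)
    config: StrandConfig | None = None
    final_states: np.ndarray | None = None

    def __post_init__(self):
        if self.vm.shape != (len(self.x), len(self.t)):
            raise ValueError("Vm matrix must be (n_nodes, n_time)")
        if not np.all(np.isfinite(self.vm)):
            raise ValueError("Vm contains non-finite values")

    def node_trace(self, k: int) -> ord.Trace:
        return ord.Trace(t=self.t, vm=self.vm[k],
                         stim_times=self.stim_times)


def build_transmural_strand(D: float = 0.127, **overrides) -> StrandConfig:
    """Default 100-node transmural strand: 25 ENDO, 35 MID, 40 EPI nodes,
    paced from the ENDO end."""
    layout = np.concatenate([
        np.full(25, int(CellType.ENDO)),
        np.full(35, int(CellType.MID)),
        np.full(40, int(CellType.EPI)),
    ])
    return StrandConfig(n_nodes=100, dx=0.15, D=D, layout=layout, **overrides)


def build_homogeneous_strand(cell_type=CellType.MID, affected_count: int = 0,
                             affected_factors=None, n_nodes: int = 100,
                             D: float = 0.127, **overrides) -> StrandConfig:
    """Homogeneous strand with a centered contiguous block of
    ``affected_count`` nodes carrying ``affected_factors``.

    For an odd left-over the extra unaffected node goes to the low-index
    side (the block shifts toward the high-index end).
    """
    if not 0 <= affected_count <= n_nodes:
        raise ValueError("affected_count out of range")
    ct = CellType(cell_type) if not isinstance(cell_type, str) \
        else CellType[cell_type.upper()]
    layout = np.full(n_nodes, int(ct))
    factors = np.ones((n_nodes, len(ord.CHANNELS)))
    lo = (n_nodes - affected_count + 1) // 2
    hi = lo + affected_count
    if affected_factors is not None and affected_count > 0:
        factors[lo:hi] = ord._factors_to_array(affected_factors)
    cfg = StrandConfig(n_nodes=n_nodes, dx=0.15, D=D, layout=layout,
                       node_factors=factors, **overrides)
    cfg.affected_span = (lo, hi)
    return cfg


# ----------------------------------------------------------------------
# solver
# ----------------------------------------------------------------------

@njit(cache=True)
def _run_strand(Y, cts, G, D, dx, dt, nsteps, stims, rec_stride, V_out):
    n = Y.shape[0]
    inf = np.empty(N_STATE)
    tau = np.empty(N_STATE)
    dy = np.empty(N_STATE)
    cur = np.empty(16)
    vold = np.empty(n)
    coef = dt * D / (dx * dx)
    nrec = V_out.shape[1]
    for i in range(nsteps):
        t = i * dt
        for k in range(n):
            vold[k] = Y[k, 0]
        if i % rec_stride == 0:
            r = i // rec_stride
            if r < nrec:
                for k in range(n):
                    V_out[k, r] = vold[k]
        for k in range(n):
            istim = 0.0
            for s in range(stims.shape[0]):
                if stims[s, 0] <= t < stims[s, 0] + stims[s, 1] \
                        and stims[s, 3] <= k <= stims[s, 4]:
                    istim += stims[s, 2]
            vm1 = vold[k - 1] if k > 0 else vold[k + 1]
            vp1 = vold[k + 1] if k < n - 1 else vold[k - 1]
            dv_diff = coef * (vm1 - 2.0 * vold[k] + vp1)
            _ord_step_node(Y[k], cts[k], G[k], istim, dt, dv_diff,
                           inf, tau, dy, cur)
            if not np.isfinite(Y[k, 0]):
                return i * 1000 + k
    return -1


# thin alias so the cell kernel is compiled once and reused here
_ord_step_node = ord._ord_step


_steady_cache: dict = {}


def _initial_states(cfg: StrandConfig) -> np.ndarray:
    """Per-node initial states from single-cell steady pacing.

    Nodes are grouped by (cell type, factor set); one representative cell
    per group is paced ``cell_prebeats`` beats at the strand BCL (a cheap
    surrogate for long tissue pre-pacing).
    """
    Y = np.empty((cfg.n_nodes, N_STATE))
    for key in {(int(ct), tuple(f)) for ct, f in
                zip(cfg.layout, map(tuple, cfg.node_factors))}:
        ct, fac = key
        cache_key = (ct, fac, cfg.bcl, cfg.cell_prebeats, cfg.dt,
                     cfg.stim_amplitude, cfg.stim_duration)
        if cache_key not in _steady_cache:
            params = CellParams(cell_type=CellType(ct),
                                stim_amplitude=cfg.stim_amplitude,
                                stim_duration=cfg.stim_duration)
            if cfg.cell_prebeats == 0:
                y = ord.init_state(CellType(ct))
            else:
                tr = ord.pace_cell(params, factors=np.array(fac),
                                   bcl=cfg.bcl, n_beats=cfg.cell_prebeats,
                                   dt=cfg.dt, rec_dt=1.0)
                y = tr.meta["final_state"]
            _steady_cache[cache_key] = y
        sel = np.array([int(c) == ct and tuple(f) == fac for c, f in
                        zip(cfg.layout, map(tuple, cfg.node_factors))])
        Y[sel] = _steady_cache[cache_key]
    return Y


def simulate_strand(cfg: StrandConfig, y0=None,
                    duration: float | None = None) -> StrandTrace:
    """Integrate a strand configuration and record the Vm field.

    Pacing applies the cell stimulus to the first ``pacing_nodes`` nodes at
    every BCL; ``extra_stims`` adds arbitrary S2-style events.  Raises
    :class:`~cardiosim.ord.NumericalBlowup` with the failing step/node on
    divergence.
    """
    if cfg.model == "surrogate":
        from . import surrogate
        return surrogate.simulate_strand_surrogate(cfg, y0=y0,
                                                   duration=duration)
    if y0 is None:
        Y = _initial_states(cfg)
    else:
        Y = np.array(y0, dtype=float)
    stim_list = []
    for b in range(cfg.n_beats):
        stim_list.append((b * cfg.bcl, cfg.stim_duration,
                          cfg.stim_amplitude, 0, cfg.pacing_nodes - 1))
    stim_list.extend(tuple(s) for s in cfg.extra_stims)
    stims = np.array(stim_list, dtype=float) if stim_list \
        else np.zeros((0, 5))
    if duration is None:
        duration = cfg.n_beats * cfg.bcl
    nsteps = int(round(duration / cfg.dt))
    stride = max(1, int(round(cfg.rec_dt / cfg.dt)))
    nrec = (nsteps + stride - 1) // stride
    V_out = np.empty((cfg.n_nodes, nrec))
    bad = _run_strand(Y, cfg.layout, cfg.node_factors, cfg.D, cfg.dx,
                      cfg.dt, nsteps, stims, stride, V_out)
    if bad >= 0:
        raise NumericalBlowup(bad // 1000, where=f"node {bad % 1000}")
    t = np.arange(nrec) * stride * cfg.dt
    return StrandTrace(t=t, vm=V_out, x=cfg.x,
                       stim_times=np.array([s[0] for s in stim_list
                                            if s[3] == 0]),
                       stim_log=stim_list, config=cfg, final_states=Y)


# ----------------------------------------------------------------------
# conduction velocity
# ----------------------------------------------------------------------

def activation_times(trace: StrandTrace, t_from: float | None = None,
                     t_to: float | None = None,
                     min_dvdt: float = 10.0) -> np.ndarray:
    """Per-node activation instants (maximum dV/dt during the upstroke)
    within a time window; NaN where no upstroke is found."""
    t = trace.t
    sel = np.ones(len(t), dtype=bool)
    if t_from is not None:
        sel &= t >= t_from
    if t_to is not None:
        sel &= t <= t_to
    ts = t[sel]
    out = np.full(trace.vm.shape[0], np.nan)
    for k in range(trace.vm.shape[0]):
        v = trace.vm[k][sel]
        dvdt = np.gradient(v, ts)
        i = int(np.argmax(dvdt))
        if dvdt[i] >= min_dvdt:
            out[k] = ts[i]
    return out


def measure_cv(trace: StrandTrace, x_start_frac: float = 0.3,
               x_end_frac: float = 0.7, beat: int = -1,
               min_dvdt: float = 10.0) -> float:
    """Planar conduction velocity (cm/s) between two fractional positions.

    Activation time is the instant of maximum dV/dt during the upstroke;
    by default the last paced beat is analyzed.  Raises
    :class:`ConductionBlock` if either measurement node fails to activate
    or activation order is degenerate.
    """
    n = trace.vm.shape[0]
    i0 = int(round(x_start_frac * (n - 1)))
    i1 = int(round(x_end_frac * (n - 1)))
    stim_times = np.sort(trace.stim_times)
    t_from = stim_times[beat] if len(stim_times) else trace.t[0]
    later = stim_times[stim_times > t_from]
    t_to = later[0] if len(later) else None
    at = activation_times(trace, t_from=t_from, t_to=t_to,
                          min_dvdt=min_dvdt)
    t0, t1 = at[i0], at[i1]
    if not (np.isfinite(t0) and np.isfinite(t1)):
        raise ConductionBlock(
            f"no activation at measurement node(s) {i0}/{i1}")
    if t1 <= t0:
        raise ConductionBlock("non-positive conduction delay")
    dist_mm = trace.x[i1] - trace.x[i0]
    return float(dist_mm / (t1 - t0) * 100.0)  # mm/ms -> cm/s
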