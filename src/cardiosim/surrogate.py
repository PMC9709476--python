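"""Two-variable surrogate excitable cell and cable.

A phenomenological excitation–recovery model (Aliev–Panfilov form) used as
a fast stand-in for the full ionic model when exercising tissue-protocol
logic (critical cell number, vulnerable window, restitution).  It shares
the strand/trace containers with the full model, mapping the dimensionless
excitation variable u onto a membrane-potential scale::

    Vm = v_rest + v_amp * u

    du/dt = ( -k u (u-a)(u-1) - u w ) / t_scale + D lap(u) + I_stim + I_ead
    dw/dt = ( eps0 + mu1 w / (u + mu2) ) * ( -w - k u (u - a - 1) ) / t_scale

An optional EAD-forcing term emulates cells predisposed to early
afterdepolarizations: an affected node re-injects a depolarizing current
for ``ead_duration`` ms starting ``ead_delay`` ms after its own
activation, producing a synchronized secondary depolarization whose
tissue-level fate (suppressed by the source–sink effect or propagated as
an ectopic beat) depends on the size of the affected region.

The surrogate reproduces the *mechanisms* the protocols probe — refractory
windows, source–sink loading, CV restitution — not human ventricular
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ord import Trace

__all__ = ["SurrogateCellParams", "simulate_strand_surrogate",
           "pace_surrogate_cell"]


@dataclass(frozen=True)
class SurrogateCellParams:
    """Aliev–Panfilov parameters plus the voltage mapping and EAD forcing."""

    k: float = 8.0
    a: float = 0.15           # excitability threshold
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    t_scale: float = 12.9     # ms per model time unit
    v_rest: float = -85.0     # mV
    v_amp: float = 110.0      # mV
    stim_amplitude: float = 0.6   # du/dt units (1/ms)
    stim_duration: float = 2.0    # ms
    ead_delay: float = 420.0      # ms after local activation
    ead_duration: float = 60.0    # ms
    ead_current: float = 0.03     # du/dt units (1/ms)
    ead_eps_scale: float = 0.55   # recovery slow-down of affected nodes
    # (prolongs their APD past the surrounding sink, as in CO-affected
    # cells, so the forced depolarization meets recovered neighbours)

    def __post_init__(self):
        if self.t_scale <= 0 or self.eps0 <= 0:
            raise ValueError("recovery time constants must be positive")


def _integrate(u, w, params, D, dx, dt, nsteps, stims, ead_mask,
               rec_stride, U_out):
    """Vectorized explicit-Euler integration; records u every rec_stride."""
    p = params
    n = len(u)
    t_act = np.full(n, -1e9)
    active = u > 0.5
    nrec = U_out.shape[1]
    for i in range(nsteps):
        t = i * dt
        if i % rec_stride == 0:
            r = i // rec_stride
            if r < nrec:
                U_out[:, r] = u
        # diffusion with mirror boundaries
        up = np.zeros(n)
        if n > 1:
            up[1:-1] = u[2:] - 2.0 * u[1:-1] + u[:-2]
            up[0] = 2.0 * (u[1] - u[0])
            up[-1] = 2.0 * (u[-2] - u[-1])
        istim = np.zeros(n)
        for s in stims:
            if s[0] <= t < s[0] + s[1]:
                istim[int(s[3]):int(s[4]) + 1] += s[2]
        # EAD forcing relative to each node's own activation time
        if ead_mask is not None:
            dtact = t - t_act
            forced = ead_mask & (dtact >= p.ead_delay) \
                & (dtact < p.ead_delay + p.ead_duration)
            istim[forced] += p.ead_current
        du = (-p.k * u * (u - p.a) * (u - 1.0) - u * w) / p.t_scale \
            + (D / (dx * dx)) * up + istim
        eps0 = np.full(n, p.eps0)
        if ead_mask is not None:
            eps0[ead_mask] *= p.ead_eps_scale
        eps = eps0 + p.mu1 * w / (u + p.mu2)
        dw = eps * (-w - p.k * u * (u - p.a - 1.0)) / p.t_scale
        u = u + dt * du
        w = w + dt * dw
        np.clip(u, -0.05, 1.5, out=u)
        # track fresh activations (upstroke crossing u = 0.5)
        newly = (~active) & (u > 0.5)
        t_act[newly] = t
        active = u > 0.5
    return u, w


def simulate_strand_surrogate(cfg, y0=None, duration=None):
    """Run a :class:`~cardiosim.strand.StrandConfig` with the surrogate
    kinetics.  Nodes whose ``node_factors`` row differs from all-ones are
    treated as EAD-forced (the surrogate has no per-channel pharmacology).
    """
    from .strand import StrandTrace
    p = cfg.surrogate_params or SurrogateCellParams()
    n = cfg.n_nodes
    dt = cfg.dt if cfg.dt <= 0.25 else 0.25
    if cfg.D > 0:  # explicit-Euler diffusion stability: D dt/dx² < 1/2
        dt = min(dt, 0.35 * cfg.dx * cfg.dx / cfg.D)
    if y0 is None:
        u = np.zeros(n)
        w = np.zeros(n)
    else:
        u = np.array(y0[:, 0], dtype=float)
        w = np.array(y0[:, 1], dtype=float)
    stim_list = [(b * cfg.bcl, p.stim_duration, p.stim_amplitude,
                  0, cfg.pacing_nodes - 1) for b in range(cfg.n_beats)]
    stim_list.extend(tuple(s) for s in cfg.extra_stims)
    ead_mask = ~np.all(cfg.node_factors == 1.0, axis=1)
    if not ead_mask.any():
        ead_mask = None
    if duration is None:
        duration = cfg.n_beats * cfg.bcl
    nsteps = int(round(duration / dt))
    stride = max(1, int(round(cfg.rec_dt / dt)))
    nrec = (nsteps + stride - 1) // stride
    U = np.empty((n, nrec))
    u, w = _integrate(u, w, p, cfg.D, cfg.dx, dt, nsteps, stim_list,
                      ead_mask, stride, U)
    t = np.arange(nrec) * stride * dt
    return StrandTrace(
        t=t, vm=p.v_rest + p.v_amp * U, x=cfg.x,
        stim_times=np.array([s[0] for s in stim_list if s[3] == 0]),
        stim_log=stim_list, config=cfg,
        final_states=np.column_stack([u, w]))


def pace_surrogate_cell(params: SurrogateCellParams | None = None,
                        bcl: float = 1000.0, n_beats: int = 1,
                        dt: float = 0.1, rec_dt: float = 0.5,
                        ead: bool = False) -> Trace:
    """Pace an isolated surrogate cell (optionally EAD-forced)."""
    p = params or SurrogateCellParams()
    u = np.zeros(1)
    w = np.zeros(1)
    stims = [(b * bcl, p.stim_duration, p.stim_amplitude, 0, 0)
             for b in range(n_beats)]
    nsteps = int(round(n_beats * bcl / dt))
    stride = max(1, int(round(rec_dt / dt)))
    nrec = (nsteps + stride - 1) // stride
    U = np.empty((1, nrec))
    mask = np.array([True]) if ead else None
    _integrate(u, w, p, 0.0, 1.0, dt, nsteps, stims, mask, stride, U)
    t = np.arange(nrec) * stride * dt
    return Trace(t=t, vm=p.v_rest + p.v_amp * U[0],
                 bcl=bcl, n_beats=n_beats, dt=dt,
                 stim_times=np.array([s[0] for s in stims]))
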