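"""Synthetic fixtures with known ground truth.

Generators for every input the analysis stages consume, with controllable
targets so each measurement can be verified by construction:

* parametric action-potential waveforms with an exact APD90 target and
  optional injected EAD deflections;
* strand activation fields whose conduction velocity is exact by
  construction;
* noisy Hill dose–response point sets drawn around known parameters;
* the placeholder disease-remodeling factor sets (clearly flagged
  synthetic stand-ins for unavailable measured magnitudes).

All generators are seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ord import Trace
from .pharmacology import (DoseResponsePoints, HillActivation, HillBlock,
                           activation_factor, block_fraction,
                           load_remodeling)

__all__ = [
    "SyntheticAPParams", "make_ap_trace", "make_strand_activation",
    "make_hill_dataset", "placeholder_remodeling",
]


@dataclass(frozen=True)
class SyntheticAPParams:
    """Waveform spec for a parametric action potential."""

    v_rest: float = -85.0       # mV
    v_peak: float = 40.0        # mV
    apd90: float = 300.0        # ms, exact target for the apd() measurement
    shape: str = "linear"       # "linear" | "exponential" repolarization
    ead_onset_frac: float = 0.5  # fraction of APD90 after the upstroke
    ead_amplitude: float = 0.0   # mV; 0 disables EAD injection
    ead_count: int = 1
    ead_width: float = 20.0      # ms
    beat_pattern: tuple = (True,)   # which beats carry the EADs
    bcl: float = 1000.0
    sample_dt: float = 0.1       # ms
    seed: int = 0

    def __post_init__(self):
        if self.v_peak <= self.v_rest:
            raise ValueError("peak must exceed resting potential")
        if self.apd90 <= 0:
            raise ValueError("APD90 target must be positive")
        if not 0.0 < self.ead_onset_frac < 1.0:
            raise ValueError("EAD onset must fall inside the AP "
                             "(onset fraction in (0,1))")
        if self.shape not in ("linear", "exponential"):
            raise ValueError(f"unknown shape {self.shape!r}")


def _single_ap(t, p: SyntheticAPParams, with_ead: bool) -> np.ndarray:
    """One AP on local time grid t >= 0 (upstroke at t = 0)."""
    amp = p.v_peak - p.v_rest
    if p.shape == "linear":
        # full repolarization time T so that the 90% level crossing
        # (rest + 0.1 amp) sits exactly at APD90
        T = p.apd90 / 0.9
        v = p.v_peak - amp * np.clip(t / T, 0.0, 1.0)
    else:
        tau = p.apd90 / np.log(10.0)   # closed-form 90% crossing
        v = p.v_rest + amp * np.exp(-t / tau)
    if with_ead and p.ead_amplitude > 0:
        for k in range(p.ead_count):
            onset = p.ead_onset_frac * p.apd90 + k * 2.0 * p.ead_width
            if onset >= p.apd90:
                raise ValueError("EAD onset after the end of the AP")
            v = v + p.ead_amplitude * np.exp(
                -0.5 * ((t - onset - p.ead_width) / (p.ead_width / 2.5)) ** 2)
    v[t < 0] = p.v_rest
    return v


def make_ap_trace(params: SyntheticAPParams, n_beats: int | None = None) -> Trace:
    """Parametric AP train whose measured APD90 equals the target within
    one sample; EADs are injected exactly as specified."""
    p = params
    pattern = list(p.beat_pattern)
    if n_beats is not None:
        pattern = (pattern * n_beats)[:n_beats]
    nb = len(pattern)
    lead = 20.0   # quiescent lead-in so the upstroke is a measurable jump
    t = np.arange(0.0, nb * p.bcl, p.sample_dt)
    v = np.full_like(t, p.v_rest)
    for b, with_ead in enumerate(pattern):
        local = t - b * p.bcl - lead
        sel = (local >= -lead) & (local < p.bcl - lead)
        v[sel] = _single_ap(local[sel], p, with_ead)
    return Trace(t=t, vm=v, bcl=p.bcl, n_beats=nb,
                 stim_times=np.arange(nb) * p.bcl,
                 meta={"params": p})


def make_strand_activation(cv_target: float, n_nodes: int = 100,
                           dx: float = 0.15,
                           ap_params: SyntheticAPParams | None = None,
                           apd_per_node=None):
    """Strand trace built from time-shifted AP copies with exact CV.

    ``cv_target`` is in cm/s.  The sample interval is snapped to an
    integer divisor of the per-node conduction delay so that activation
    instants fall exactly on the time grid and the measured CV equals the
    target exactly.  ``apd_per_node`` optionally grades APD along the
    strand (e.g. longer endocardial APD for an upright T wave).
    """
    from .strand import StrandTrace
    if cv_target <= 0:
        raise ValueError("cv_target must be positive")
    p = ap_params or SyntheticAPParams()
    delay = dx / (cv_target / 100.0)          # ms per node
    k = max(1, int(round(delay / p.sample_dt)))
    dt_s = delay / k                           # exact divisor of the delay
    t_total = n_nodes * delay + p.bcl
    t = np.arange(0.0, t_total, dt_s)
    vm = np.empty((n_nodes, len(t)))
    lead = 20.0   # quiescent lead-in before the first upstroke
    for node in range(n_nodes):
        pn = p if apd_per_node is None else _with_apd(p, apd_per_node[node])
        vm[node] = _single_ap(t - lead - node * delay, pn, False)
    return StrandTrace(t=t, vm=vm, x=(np.arange(n_nodes) + 0.5) * dx,
                       stim_times=np.array([0.0]),
                       stim_log=[(0.0, 1.0, -80.0, 0, 0)])


def _with_apd(p: SyntheticAPParams, apd90: float) -> SyntheticAPParams:
    from dataclasses import replace
    return replace(p, apd90=float(apd90))


def make_hill_dataset(truth, doses, noise_sd: float = 0.0,
                      seed: int = 0) -> DoseResponsePoints:
    """Dose–response points from a known Hill truth plus Gaussian noise.

    ``truth`` is a :class:`~cardiosim.pharmacology.HillBlock` (responses
    are blocked fractions) or :class:`HillActivation` (responses are
    fold-activations).
    """
    doses = np.asarray(doses, dtype=float)
    if isinstance(truth, HillBlock):
        resp = block_fraction(doses, truth)
    elif isinstance(truth, HillActivation):
        resp = activation_factor(doses, truth)
    else:
        raise TypeError("truth must be HillBlock or HillActivation")
    rng = np.random.default_rng(seed)
    resp = resp + rng.normal(0.0, noise_sd, size=doses.shape)
    return DoseResponsePoints(doses=doses, responses=resp)


def placeholder_remodeling(condition: str):
    """Clearly-flagged synthetic disease-remodeling factor set.

    Returns (ConductanceFactors, metadata); the metadata carries the
    provenance flag marking the values as package-authored placeholders,
    qualitatively consistent with the condition (CO enhances I_NaL and
    depresses I_Na/I_CaL/I_K1/I_Kr; HF reduces the repolarization
    reserve) but not measured magnitudes.
    """
    return load_remodeling(condition)
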