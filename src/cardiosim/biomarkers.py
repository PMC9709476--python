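"""Cellular and pseudo-ECG biomarkers.

* APD_level: action potential duration from the maximum-upstroke instant to
  the downward crossing of ``rest + (1 - level/100) * amplitude`` (linear
  interpolation between samples).
* EAD detection: a secondary depolarization during repolarization — the
  membrane derivative turns from negative to positive while Vm is still in
  the plateau window (onset above -40 mV by default) with a prominence of
  at least 2 mV.
* Pseudo-ECG: the extracellular unipolar potential of a 1D strand,

      phi_e(x') = (a^2/4) * integral( -dVm/dx * d/dx(1/r) dx )

  evaluated with central spatial gradients; r is the distance from each
  node to the electrode, a the strand radius.  phi_e is in arbitrary units.
* QT interval: earliest QRS deflection (threshold crossing above baseline
  noise) to the return of the T-wave descending limb to the TP baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiomarkerError", "ECGTrace", "EADReport", "apd", "detect_eads",
    "pseudo_ecg", "measure_qt", "transmural_dispersion",
]


class BiomarkerError(ValueError):
    """A biomarker is undefined for the given trace (no AP, no QRS,
    repolarization failure, ...)."""


@dataclass
class ECGTrace:
    """Pseudo-ECG series (arbitrary units)."""

    t: np.ndarray
    phi: np.ndarray
    electrode_mm: float | None = None   # position along the strand axis
    radius_mm: float | None = None
    stim_times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.t.shape != self.phi.shape:
            raise ValueError("time and phi series must match")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi contains non-finite values")


# ----------------------------------------------------------------------
# action potential duration
# ----------------------------------------------------------------------

_UPSTROKE_DVDT = 10.0   # mV/ms; minimum dV/dt to call an upstroke


def apd(trace, level: float = 90.0, dvdt_min: float = _UPSTROKE_DVDT) -> float:
    """APD at a repolarization level (ms) for the first AP in a trace."""
    t = np.asarray(trace.t, dtype=float)
    v = np.asarray(trace.vm, dtype=float)
    if len(t) < 3:
        raise BiomarkerError("trace too short")
    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(dvdt))
    if dvdt[i_up] < dvdt_min:
        raise BiomarkerError("no AP: upstroke dV/dt below threshold")
    v_rest = v[: max(i_up, 1)].min() if i_up > 0 else v[0]
    i_peak = i_up + int(np.argmax(v[i_up:]))
    amplitude = v[i_peak] - v_rest
    if amplitude <= 0:
        raise BiomarkerError("no AP: non-positive amplitude")
    v_level = v_rest + (1.0 - level / 100.0) * amplitude
    seg = v[i_peak:]
    below = np.nonzero(seg < v_level)[0]
    if len(below) == 0:
        raise BiomarkerError("repolarization failure: level never crossed")
    k = i_peak + below[0]
    # linear interpolation across the crossing
    if k == 0 or v[k - 1] == v[k]:
        t_cross = t[k]
    else:
        frac = (v[k - 1] - v_level) / (v[k - 1] - v[k])
        t_cross = t[k - 1] + frac * (t[k] - t[k - 1])
    return float(t_cross - t[i_up])


def transmural_dispersion(apd_by_type: dict) -> dict:
    """MID-ENDO and MID-EPI APD differences (ms)."""
    for key in ("ENDO", "MID", "EPI"):
        if key not in apd_by_type:
            raise ValueError(f"missing cell type {key}")
    return {
        "MID-ENDO": float(apd_by_type["MID"] - apd_by_type["ENDO"]),
        "MID-EPI": float(apd_by_type["MID"] - apd_by_type["EPI"]),
    }


# ----------------------------------------------------------------------
# early afterdepolarizations
# ----------------------------------------------------------------------

@dataclass
class EADReport:
    counts: list            # per-beat EAD counts
    onset_times: list       # ms, flattened over beats
    amplitudes: list        # mV prominence of each EAD
    pattern: str            # "none" | "1:1" | "<n>:1" | "irregular"

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def _eads_in_segment(t, v, v_onset_min, prominence):
    """EADs in one beat: local minima during repolarization followed by a
    rebound of at least `prominence` mV, with the minimum above
    `v_onset_min`."""
    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(dvdt))
    if dvdt[i_up] < _UPSTROKE_DVDT:
        return [], []
    i_peak = i_up + int(np.argmax(v[i_up:]))
    onsets, amps = [], []
    i = i_peak + 1
    n = len(v)
    while i < n - 1:
        if v[i] < v[i - 1] and v[i] <= v[i + 1]:     # local minimum
            v_min = v[i]
            j = i + 1
            while j < n - 1 and v[j + 1] >= v[j]:
                j += 1
            rebound = v[j] - v_min
            if rebound >= prominence and v_min >= v_onset_min:
                onsets.append(float(t[i]))
                amps.append(float(rebound))
            i = j + 1
        else:
            i += 1
    return onsets, amps


def detect_eads(trace, v_onset_min: float = -40.0,
                prominence: float = 2.0) -> EADReport:
    """Detect EADs beat-by-beat and label the beat pattern."""
    t = np.asarray(trace.t, dtype=float)
    v = np.asarray(trace.vm, dtype=float)
    stim_times = getattr(trace, "stim_times", None)
    if stim_times is not None and len(stim_times) > 1:
        edges = [st for st in stim_times if t[0] <= st <= t[-1]]
        if not edges or edges[0] > t[0]:
            edges = [t[0]] + edges
        edges.append(t[-1] + 1.0)
    else:
        edges = [t[0], t[-1] + 1.0]

    counts, onsets, amps = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (t >= lo) & (t < hi)
        if sel.sum() < 5:
            continue
        o, a = _eads_in_segment(t[sel], v[sel], v_onset_min, prominence)
        counts.append(len(o))
        onsets.extend(o)
        amps.extend(a)

    if not counts or all(c == 0 for c in counts):
        pattern = "none"
    elif all(c >= 1 for c in counts):
        pattern = "1:1"
    else:
        pattern = "irregular"
        flags = [1 if c >= 1 else 0 for c in counts]
        for period in range(2, len(flags) + 1):
            if all(flags[k] == (1 if k % period == period - 1 else 0)
                   for k in range(len(flags))) or \
               all(flags[k] == (1 if k % period == 0 else 0)
                   for k in range(len(flags))):
                pattern = f"{period}:1"
                break
    return EADReport(counts=counts, onset_times=onsets, amplitudes=amps,
                     pattern=pattern)


# ----------------------------------------------------------------------
# pseudo-ECG
# ----------------------------------------------------------------------

def pseudo_ecg(strand_trace, electrode_mm: float | None = None,
               radius_mm: float = 1.1) -> ECGTrace:
    """Unipolar pseudo-ECG of a strand trace.

    The electrode sits on the strand axis; by default 20 mm beyond the
    distal (high-x) end.  Raises if the electrode coincides with a node.
    """
    x = np.asarray(strand_trace.x, dtype=float)          # mm, per node
    vm = np.asarray(strand_trace.vm, dtype=float)        # node x time
    t = np.asarray(strand_trace.t, dtype=float)
    if electrode_mm is None:
        electrode_mm = float(x[-1] + 20.0)
    r = np.abs(electrode_mm - x)
    if np.any(r < 1e-9):
        raise ValueError("electrode coincides with a strand node")
    dx = float(x[1] - x[0])
    # -dVm/dx, central differences (one-sided at the ends)
    grad_v = np.gradient(vm, x, axis=0)
    # d/dx (1/r) along the axis
    dinv_r = (electrode_mm - x) / r ** 3
    phi = (radius_mm ** 2 / 4.0) * np.sum(
        (-grad_v) * dinv_r[:, None] * dx, axis=0)
    return ECGTrace(t=t, phi=phi, electrode_mm=electrode_mm,
                    radius_mm=radius_mm,
                    stim_times=getattr(strand_trace, "stim_times", None))


# ----------------------------------------------------------------------
# QT interval
# ----------------------------------------------------------------------

def measure_qt(ecg: ECGTrace, qrs_threshold_frac: float = 0.05,
               tend_tol_frac: float = 0.02, qrs_window_ms: float = 80.0,
               baseline_window_ms: float = 20.0,
               t_threshold_frac: float = 0.01) -> dict:
    """QT interval and its landmarks from a single-beat pseudo-ECG.

    QRS onset: first sample where |phi - baseline| exceeds
    ``qrs_threshold_frac`` of the peak |QRS| deflection.  T end: first
    return of the descending limb after the T peak to within
    ``tend_tol_frac`` of the T amplitude of the TP baseline.
    """
    t = ecg.t
    phi = ecg.phi
    stim_times = ecg.stim_times
    if stim_times is not None and len(stim_times) > 0:
        stims = [st for st in stim_times if t[0] <= st <= t[-1]]
        t_stim = stims[-1] if stims else t[0]
    else:
        t_stim = t[0]
    base_sel = (t >= t_stim - baseline_window_ms) & (t < t_stim)
    baseline = float(np.mean(phi[base_sel])) if base_sel.any() else float(phi[0])
    dev = phi - baseline
    after = t >= t_stim
    if not after.any():
        raise BiomarkerError("no samples after the stimulus")
    ta = t[after]
    da = dev[after]

    qrs_sel = ta <= ta[0] + qrs_window_ms
    peak_qrs = float(np.max(np.abs(da[qrs_sel])))
    if peak_qrs <= 0 or not np.any(np.abs(da[qrs_sel]) >
                                   qrs_threshold_frac * peak_qrs):
        raise BiomarkerError("no QRS detected")
    i_on = int(np.argmax(np.abs(da) > qrs_threshold_frac * peak_qrs))
    t_onset = float(ta[i_on])

    t_sel = ta > ta[0] + qrs_window_ms
    if not t_sel.any():
        raise BiomarkerError("trace ends before the T wave")
    i_tpk_rel = int(np.argmax(np.abs(da[t_sel])))
    idx_t = np.nonzero(t_sel)[0]
    i_tpk = idx_t[i_tpk_rel]
    t_amp = float(da[i_tpk])
    if abs(t_amp) < t_threshold_frac * peak_qrs:
        raise BiomarkerError("no T wave detected")
    tol = abs(t_amp) * tend_tol_frac
    desc = np.abs(da[i_tpk:]) <= tol
    if not desc.any():
        raise BiomarkerError("repolarization failure: T wave does not "
                             "return to baseline")
    i_end = i_tpk + int(np.argmax(desc))
    t_end = float(ta[i_end])
    return {
        "qt_ms": t_end - t_onset,
        "qrs_onset_ms": t_onset,
        "t_end_ms": t_end,
        "t_peak_ms": float(ta[i_tpk]),
        "t_amplitude": t_amp,
        "baseline": baseline,
    }
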