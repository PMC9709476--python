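"""Arrhythmia-risk protocols on cells and strands.

* CV dynamic restitution: pace a strand at progressively shorter basic
  cycle lengths (starting from 3000 ms), record the steady conduction
  velocity per BCL, stop at conduction failure.
* Vulnerable window (S1–S2): after a planar S1 wave, a local S2 test
  stimulus is applied at a node over a scanned range of coupling
  intervals; each outcome is classified blocked / unidirectional /
  bidirectional, and the vulnerable window is the contiguous band of
  unidirectional intervals.
* Critical cell number (source–sink): on a homogeneous strand whose
  centered block of N cells is predisposed to EADs, find the smallest N
  whose synchronized afterdepolarizations overcome the source–sink effect
  and fire a propagated ectopic beat.
* Population of models: scale the nine major conductances by i.i.d.
  normal factors (mean 1.0, sd 0.2 by default), pace every variant, and
  report APD90 and the fraction of variants with EADs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biomarkers, ord, strand
from .ord import CellParams, CellType
from .pharmacology import ConductanceFactors, compose_factors
from .strand import ConductionBlock, StrandConfig, measure_cv, simulate_strand

__all__ = [
    "RestitutionCurve", "VWResult", "CriticalMassResult", "PopulationSpec",
    "cv_restitution", "vulnerable_window", "critical_cell_number",
    "sample_population", "run_population",
]


# ----------------------------------------------------------------------
# CV restitution
# ----------------------------------------------------------------------

@dataclass
class RestitutionCurve:
    bcls: list                  # ms, strictly decreasing
    cvs: list                   # cm/s
    termination: str | None = None   # None or "conduction failure"
    failed_bcl: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bcl_ms": self.bcls, "cv_cm_s": self.cvs})


def cv_restitution(cfg: StrandConfig, bcl_schedule,
                   max_beats: int = 20, cv_tol: float = 0.005,
                   min_dvdt: float = 10.0) -> RestitutionCurve:
    """Dynamic restitution: for each BCL pace until the steady criterion
    (CV change < ``cv_tol`` between consecutive beats, capped at
    ``max_beats``), record CV; stop at the first conduction failure.

    The strand state is carried from one BCL to the next.
    """
    bcls = list(bcl_schedule)
    if any(b2 >= b1 for b1, b2 in zip(bcls, bcls[1:])):
        raise ValueError("BCL schedule must be strictly decreasing")
    out_b, out_cv = [], []
    y0 = None
    for bcl in bcls:
        c = _with(cfg, bcl=bcl, n_beats=1)
        cv = None
        prev = None
        try:
            for _ in range(max_beats):   # beat-by-beat until CV is steady
                tr = simulate_strand(c, y0=y0)
                y0 = tr.final_states
                cv = measure_cv(tr, beat=0, min_dvdt=min_dvdt)
                if prev is not None and abs(cv - prev) < cv_tol * prev:
                    break
                prev = cv
        except ConductionBlock:
            if cv is None:
                return RestitutionCurve(out_b, out_cv,
                                        termination="conduction failure",
                                        failed_bcl=bcl)
        out_b.append(bcl)
        out_cv.append(cv)
    return RestitutionCurve(out_b, out_cv)


def _with(cfg: StrandConfig, **kw) -> StrandConfig:
    d = dict(
        n_nodes=cfg.n_nodes, dx=cfg.dx, D=cfg.D, layout=cfg.layout.copy(),
        node_factors=cfg.node_factors.copy(), pacing_nodes=cfg.pacing_nodes,
        bcl=cfg.bcl, n_beats=cfg.n_beats, dt=cfg.dt,
        stim_amplitude=cfg.stim_amplitude, stim_duration=cfg.stim_duration,
        cell_prebeats=cfg.cell_prebeats, extra_stims=list(cfg.extra_stims),
        rec_dt=cfg.rec_dt, model=cfg.model,
        surrogate_params=cfg.surrogate_params)
    d.update(kw)
    return StrandConfig(**d)


# ----------------------------------------------------------------------
# vulnerable window
# ----------------------------------------------------------------------

@dataclass
class VWResult:
    windows: dict          # node -> (start_ci, end_ci, width_ms)
    mean_width: float      # ms
    outcomes: dict         # node -> {ci: "blocked"|"unidirectional"|"bidirectional"}


def _count_acts_after(vm, t, t0, thresh=-20.0):
    sel = t >= t0
    above = vm[sel] > thresh
    return int((np.diff(above.astype(int)) == 1).sum()) \
        + int(above[0] and False)


def vulnerable_window(cfg: StrandConfig, s2_nodes, ci_range,
                      ci_step: float = 1.0, probe_offset: int = 10,
                      s2_amplitude: float | None = None,
                      s2_duration: float | None = None,
                      tail_ms: float = 400.0) -> VWResult:
    """S1–S2 vulnerable-window scan.

    An S1 planar wave is launched from the pacing end at t = 0; for each
    tested node and coupling interval CI (ms after the S1 stimulus) an S2
    stimulus is applied at that node, and the outcome is classified by
    whether fresh activations appear at probe nodes ``probe_offset`` nodes
    on either side: none = blocked, one side = unidirectional,
    both = bidirectional.  The VW is the contiguous unidirectional band.
    """
    # a single-node S2 faces a large diffusive sink: defaults are stronger
    # and longer than the planar S1 stimulus
    if cfg.model == "ord":
        amp = s2_amplitude if s2_amplitude is not None \
            else 2.0 * cfg.stim_amplitude
        dur = s2_duration if s2_duration is not None else 2.0
    else:
        amp = s2_amplitude if s2_amplitude is not None else 2.0
        dur = s2_duration if s2_duration is not None else 5.0
    cis = np.arange(ci_range[0], ci_range[1] + ci_step / 2, ci_step)
    windows, outcomes = {}, {}
    base = _with(cfg, n_beats=1)
    # S1-only reference run to know prior activation structure
    for node in s2_nodes:
        lo = max(0, node - probe_offset)
        hi = min(cfg.n_nodes - 1, node + probe_offset)
        cls = {}
        for ci in cis:
            c = _with(base, extra_stims=[(ci, dur, amp, node, node)])
            tr = simulate_strand(c, duration=ci + tail_ms)
            t_chk = ci + dur
            retro = _count_acts_after(tr.vm[lo], tr.t, t_chk) >= 1
            ante = _count_acts_after(tr.vm[hi], tr.t, t_chk) >= 1
            if retro and ante:
                cls[float(ci)] = "bidirectional"
            elif retro or ante:
                cls[float(ci)] = "unidirectional"
            else:
                cls[float(ci)] = "blocked"
        outcomes[node] = cls
        uni = [ci for ci, lab in cls.items() if lab == "unidirectional"]
        if uni:
            windows[node] = (min(uni), max(uni), max(uni) - min(uni))
        else:
            windows[node] = (np.nan, np.nan, 0.0)
    mean_width = float(np.mean([w[2] for w in windows.values()]))
    return VWResult(windows=windows, mean_width=mean_width,
                    outcomes=outcomes)


# ----------------------------------------------------------------------
# critical cell number
# ----------------------------------------------------------------------

@dataclass
class CriticalMassResult:
    critical_count: int | None     # None if no count up to n_nodes fires
    length_mm: float | None
    search_trace: dict             # tested count -> ectopic (bool)
    method: str = "linear"


def _ectopic(tr: strand.StrandTrace, frac_nodes: float = 0.9,
             thresh: float = -20.0) -> bool:
    """Propagated ectopic beat: at least ``frac_nodes`` of all nodes
    activate a second time (beyond the single paced S1 wave)."""
    above = tr.vm > thresh
    counts = (np.diff(above.astype(int), axis=1) == 1).sum(axis=1)
    return bool((counts >= 2).mean() >= frac_nodes)


def critical_cell_number(make_cfg, n_nodes: int = 100,
                         method: str = "linear", step: int = 1,
                         duration: float | None = None) -> CriticalMassResult:
    """Smallest centered affected-block size that fires a propagated
    ectopic beat.

    ``make_cfg(count)`` must return the strand configuration for a given
    affected count (see :func:`cardiosim.strand.build_homogeneous_strand`).
    ``method`` is "linear" (gradually increasing counts, as in the source
    protocol) or "bisect" (after verifying monotonicity at the threshold).
    """
    trace = {}

    def fires(count):
        if count not in trace:
            cfg = make_cfg(count)
            tr = simulate_strand(cfg, duration=duration)
            trace[count] = _ectopic(tr)
        return trace[count]

    if fires(0):
        raise RuntimeError("baseline (no affected cells) already fires "
                           "an ectopic beat; detector misconfigured")
    crit = None
    if method == "linear":
        for count in range(step, n_nodes + 1, step):
            if fires(count):
                crit = count
                break
    elif method == "bisect":
        lo, hi = 0, n_nodes
        if not fires(n_nodes):
            hi = None
        else:
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if fires(mid):
                    hi = mid
                else:
                    lo = mid
            crit = hi
    else:
        raise ValueError(f"unknown search method {method!r}")
    if crit is not None and crit >= 1:
        # monotonicity spot check at threshold ± 1
        assert not fires(crit - 1) and fires(crit)
    dx = make_cfg(0).dx
    return CriticalMassResult(
        critical_count=crit,
        length_mm=None if crit is None else crit * dx,
        search_trace=dict(sorted(trace.items())), method=method)


# ----------------------------------------------------------------------
# population of models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Conductance-scaling population: each of the nine channels of every
    variant gets an i.i.d. factor ~ N(mean, sd), negatives redrawn."""

    n_variants: int = 1000
    mean: float = 1.0
    sd: float = 0.2
    channels: tuple = ord.CHANNELS
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def sample_population(spec: PopulationSpec) -> list:
    """Reproducible list of per-variant ConductanceFactors."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_variants):
        fac = {}
        for ch in spec.channels:
            f = rng.normal(spec.mean, spec.sd)
            while f < 0:   # truncate: negative conductance is unphysical
                f = rng.normal(spec.mean, spec.sd)
            fac[ch] = float(f)
        out.append(ConductanceFactors(fac))
    return out


@dataclass
class PopulationResult:
    table: pd.DataFrame
    ead_ratio: float           # among variants that completed
    n_failed: int              # numerical blow-ups, excluded


def run_population(spec: PopulationSpec, condition_factors=None,
                   cell_type=CellType.MID, bcl: float = 1000.0,
                   n_beats: int = 3, dt: float = 0.005,
                   ead_kwargs: dict | None = None) -> PopulationResult:
    """Pace every population variant (condition factors composed with the
    variant's own factors) and collect APD90 and EAD flags."""
    variants = sample_population(spec)
    ct = CellType[cell_type.upper()] if isinstance(cell_type, str) \
        else CellType(cell_type)
    params = CellParams(cell_type=ct)
    rows = []
    n_failed = 0
    for i, vf in enumerate(variants):
        fac = vf if condition_factors is None \
            else compose_factors(condition_factors, vf)
        try:
            tr = ord.pace_cell(params, factors=fac, bcl=bcl,
                               n_beats=n_beats, dt=dt, record_all=True)
        except ord.NumericalBlowup:
            n_failed += 1
            rows.append({"variant": i, "apd90_ms": np.nan,
                         "ead_count": np.nan, "ead": np.nan,
                         "failed": True})
            continue
        rep = biomarkers.detect_eads(tr, **(ead_kwargs or {}))
        # APD of the final beat (NaN on repolarization failure)
        t0 = tr.stim_times[-1]
        sel = tr.t >= t0
        try:
            apd90 = biomarkers.apd(ord.Trace(t=tr.t[sel], vm=tr.vm[sel]))
        except biomarkers.BiomarkerError:
            apd90 = np.nan
        rows.append({"variant": i, "apd90_ms": apd90,
                     "ead_count": rep.total,
                     "ead": rep.total > 0, "failed": False})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    ratio = float(ok["ead"].mean()) if len(ok) else np.nan
    return PopulationResult(table=table, ead_ratio=ratio, n_failed=n_failed)
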