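"""Human ventricular myocyte electrophysiology.

The membrane kinetics follow the O'Hara–Rudy dynamics (ORd) human
ventricular model for ENDO, MID and EPI cell types, with one substitution:
the fast sodium current I_Na is replaced by the ten Tusscher (TNNP06)
formulation (gates m, h, j and its maximal conductance), which produces
physiological conduction velocities in coupled tissue.  CaMK modulation
tied to the original ORd I_Na is dropped together with the substitution.

Membrane charge balance::

    dVm/dt = -(I_ion + I_stim) / Cm

where I_ion is the sum of all transmembrane ionic currents and I_stim is
the externally applied stimulus.

Numerics: operator-split forward Euler for Vm, ion concentrations and
CaMK, with Rush–Larsen exponential integration for every gating (and
relaxation-form) variable.  Default fixed step dt = 0.005 ms.

Nine currents are scalable through multiplicative :class:`ConductanceFactors`
(see :mod:`cardiosim.pharmacology`): I_Na, I_NaL, I_CaL, I_to, I_Kr, I_Ks,
I_K1, I_NaCa, I_NaK.  A factor of 1 leaves the current untouched; a factor
of 0 annihilates it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from importlib import resources

import numpy as np
from numba import njit

__all__ = [
    "CellType",
    "CellParams",
    "Trace",
    "CHANNELS",
    "STATE_NAMES",
    "CURRENT_NAMES",
    "init_state",
    "compute_currents",
    "step_cell",
    "pace_cell",
    "run_unstimulated",
]


class CellType(IntEnum):
    """Transmural ventricular cell type (determines the published ORd
    parameter variants)."""

    ENDO = 0
    EPI = 1
    MID = 2


#: channel identifiers of the nine scalable currents, in factor-array order
CHANNELS = ("I_Na", "I_NaL", "I_CaL", "I_to", "I_Kr", "I_Ks", "I_K1",
            "I_NaCa", "I_NaK")

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "h", "j",
    "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)
N_STATE = len(STATE_NAMES)

CURRENT_NAMES = (
    "I_Na", "I_NaL", "I_CaL", "I_CaNa", "I_CaK", "I_to", "I_Kr", "I_Ks",
    "I_K1", "I_NaCa", "I_NaK", "I_Nab", "I_Cab", "I_Kb", "I_pCa", "I_ion",
)

# state-vector partition for the integrator
_GATE_LO, _GATE_HI = 9, 37          # indices 9..36: Rush–Larsen states
_EULER_IDX = (1, 2, 3, 4, 5, 6, 7, 8, 37)

# baseline (ENDO) maximal conductances / permeabilities of the nine
# scalable currents, in CHANNELS order
BASE_G = np.array([14.838, 0.0075, 0.0001, 0.02, 0.046, 0.0034, 0.1908,
                   0.0008, 30.0])


@dataclass(frozen=True)
class CellParams:
    """Myocyte parameters.

    Conductances are the baseline (ENDO) values of the nine scalable
    currents; transmural multipliers for MID/EPI are applied internally.
    ``stim_amplitude`` is in µA/µF (negative = depolarizing),
    ``stim_duration`` in ms.
    """

    cell_type: CellType = CellType.ENDO
    cm: float = 1.0                       # µF/cm²
    gna: float = 14.838                   # mS/µF (TNNP06)
    gnal: float = 0.0075
    pcal: float = 0.0001
    gto: float = 0.02
    gkr: float = 0.046
    gks: float = 0.0034
    gk1: float = 0.1908
    gncx: float = 0.0008
    pnak: float = 30.0
    stim_amplitude: float = -80.0
    stim_duration: float = 0.5

    def __post_init__(self):
        if self.cm <= 0:
            raise ValueError("Cm must be positive")
        for name in ("gna", "gnal", "pcal", "gto", "gkr", "gks", "gk1",
                     "gncx", "pnak"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if not isinstance(self.cell_type, CellType):
            object.__setattr__(self, "cell_type", CellType(self.cell_type))

    def multipliers(self, factors=None) -> np.ndarray:
        """Effective per-channel multipliers relative to the hard-coded
        baseline, combining parameter overrides with drug/disease factors."""
        own = np.array([self.gna, self.gnal, self.pcal, self.gto, self.gkr,
                        self.gks, self.gk1, self.gncx, self.pnak]) / BASE_G
        if factors is not None:
            own = own * _factors_to_array(factors)
        return own


def _factors_to_array(factors) -> np.ndarray:
    """Accept a ConductanceFactors-like mapping, a 9-array, or None."""
    if factors is None:
        return np.ones(len(CHANNELS))
    if hasattr(factors, "as_array"):
        return factors.as_array()
    arr = np.asarray(
        [factors.get(c, 1.0) for c in CHANNELS] if isinstance(factors, dict)
        else factors, dtype=float)
    if arr.shape != (len(CHANNELS),):
        raise ValueError("factors must map the nine scalable channels")
    if np.any(arr < 0):
        raise ValueError("conductance factors must be >= 0")
    return arr


@dataclass
class Trace:
    """Uniformly sampled single-cell recording."""

    t: np.ndarray                 # ms
    vm: np.ndarray                # mV
    currents: dict | None = None  # optional per-current series (µA/µF)
    bcl: float | None = None
    n_beats: int | None = None
    dt: float | None = None
    steady: bool | None = None    # |ΔAPD90| < 1 ms over the last two beats
    apd_history: list | None = None
    stim_times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.t.shape != self.vm.shape:
            raise ValueError("time and Vm series must have equal length")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")


# ----------------------------------------------------------------------
# model kernel
# ----------------------------------------------------------------------

@njit(cache=True)
def _ord_eval(y, ct, g, istim, inf, tau, dy, cur):
    """Evaluate all currents, gate targets/time constants and Euler rates.

    y    : state vector (N_STATE)
    ct   : 0 ENDO, 1 EPI, 2 MID
    g    : per-channel multipliers in CHANNELS order
    inf/tau : filled for Rush–Larsen states (indices 9..36)
    dy   : filled for Euler states (v, concentrations, CaMKt)
    cur  : filled with CURRENT_NAMES values
    """
    v = y[0]
    nai = y[1]; nass = y[2]; ki = y[3]; kss = y[4]
    cai = y[5]; cass = y[6]; cansr = y[7]; cajsr = y[8]
    m = y[9]; h = y[10]; jg = y[11]
    mL = y[12]; hL = y[13]; hLp = y[14]
    a = y[15]; iF = y[16]; iS = y[17]; ap = y[18]; iFp = y[19]; iSp = y[20]
    d = y[21]; ff = y[22]; fs = y[23]; fcaf = y[24]; fcas = y[25]
    jca = y[26]; nca = y[27]; ffp = y[28]; fcafp = y[29]
    xrf = y[30]; xrs = y[31]; xs1 = y[32]; xs2 = y[33]; xk1 = y[34]
    Jrelnp = y[35]; Jrelp = y[36]; CaMKt = y[37]

    # physical constants / geometry
    nao = 140.0; cao = 1.8; ko = 5.4
    R = 8314.0; T = 310.0; F = 96485.0
    L = 0.01; rad = 0.0011
    vcell = 1000.0 * 3.14 * rad * rad * L
    Ageo = 2.0 * 3.14 * rad * rad + 2.0 * 3.14 * rad * L
    Acap = 2.0 * Ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    # CaMK
    KmCaMK = 0.15
    aCaMK = 0.05; bCaMK = 0.00068; CaMKo = 0.05; KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dy[37] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt
    fphos = 1.0 / (1.0 + KmCaMK / CaMKa)

    # reversal potentials
    ENa = (R * T / F) * np.log(nao / nai)
    EK = (R * T / F) * np.log(ko / ki)
    PKNa = 0.01833
    EKs = (R * T / F) * np.log((ko + PKNa * nao) / (ki + PKNa * nai))
    vfrt = v * F / (R * T)
    vffrt = v * F * F / (R * T)

    # --- I_Na (TNNP06 fast sodium current) ---
    mss = 1.0 / ((1.0 + np.exp((-56.86 - v) / 9.03)) ** 2)
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    inf[9] = mss; tau[9] = am * bm
    hss = 1.0 / ((1.0 + np.exp((v + 71.55) / 7.43)) ** 2)
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    inf[10] = hss; tau[10] = 1.0 / (ah + bh)
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        aj = (-2.5428e4 * np.exp(0.2444 * v)
              - 6.948e-6 * np.exp(-0.04391 * v)) * (v + 37.78) \
            / (1.0 + np.exp(0.311 * (v + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * v) \
            / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    inf[11] = hss; tau[11] = 1.0 / (aj + bj)
    GNa = 14.838 * g[0]
    INa = GNa * m * m * m * h * jg * (v - ENa)

    # --- I_NaL ---
    mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    tmL = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                 + 8.552 * np.exp(-(v + 77.42) / 5.955))
    inf[12] = mLss; tau[12] = tmL
    hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    inf[13] = hLss; tau[13] = 200.0
    hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    inf[14] = hLssp; tau[14] = 600.0
    GNaL = 0.0075 * g[1]
    if ct == 1:
        GNaL *= 0.6
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fphos) * hL + fphos * hLp)

    # --- I_to ---
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    inf[15] = ass; tau[15] = ta
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    if ct == 1:
        delta_epi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    inf[16] = iss; tau[16] = tiF
    inf[17] = iss; tau[17] = tiS
    AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    inf[18] = assp; tau[18] = ta
    dti_develop = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                    + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    inf[19] = iss; tau[19] = dti_develop * dti_recover * tiF
    inf[20] = iss; tau[20] = dti_develop * dti_recover * tiS
    ip_gate = AiF * iFp + AiS * iSp
    Gto = 0.02 * g[3]
    if ct == 1 or ct == 2:
        Gto *= 4.0
    Ito = Gto * (v - EK) * ((1.0 - fphos) * a * i_gate + fphos * ap * ip_gate)

    # --- I_CaL / I_CaNa / I_CaK ---
    dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    inf[21] = dss; tau[21] = td
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    inf[22] = fss; tau[22] = tff
    inf[23] = fss; tau[23] = tfs
    Aff = 0.6
    Afs = 1.0 - Aff
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    inf[24] = fcass; tau[24] = tfcaf
    inf[25] = fcass; tau[25] = tfcas
    fca = Afcaf * fcaf + Afcas * fcas
    inf[26] = fcass; tau[26] = 75.0
    inf[28] = fss; tau[28] = 2.5 * tff
    fp = Aff * ffp + Afs * fs
    inf[29] = fcass; tau[29] = 2.5 * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002; k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    inf[27] = anca * k2n / km2n
    tau[27] = 1.0 / km2n

    # GHK driving forces (guard the removable singularity at v = 0)
    vv = vfrt if np.abs(vfrt) > 1e-8 else 1e-8
    ex1 = np.exp(vv)
    ex2 = np.exp(2.0 * vv)
    PhiCaL = 4.0 * vffrt * (cass * ex2 - 0.341 * cao) / (ex2 - 1.0)
    PhiCaNa = 1.0 * vffrt * (0.75 * nass * ex1 - 0.75 * nao) / (ex1 - 1.0)
    PhiCaK = 1.0 * vffrt * (0.75 * kss * ex1 - 0.75 * ko) / (ex1 - 1.0)
    PCa = 0.0001 * g[2]
    if ct == 1:
        PCa *= 1.2
    elif ct == 2:
        PCa *= 2.5
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    ICaL = (1.0 - fphos) * PCa * PhiCaL * d * (f * (1.0 - nca)
                                               + jca * fca * nca) \
        + fphos * PCap * PhiCaL * d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaNa = (1.0 - fphos) * PCaNa * PhiCaNa * d * (f * (1.0 - nca)
                                                   + jca * fca * nca) \
        + fphos * PCaNap * PhiCaNa * d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaK = (1.0 - fphos) * PCaK * PhiCaK * d * (f * (1.0 - nca)
                                                + jca * fca * nca) \
        + fphos * PCaKp * PhiCaK * d * (fp * (1.0 - nca) + jca * fcap * nca)

    # --- I_Kr ---
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    inf[30] = xrss; tau[30] = txrf
    inf[31] = xrss; tau[31] = txrs
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = 1.0 / (1.0 + np.exp((v + 55.0) / 75.0)) \
        * 1.0 / (1.0 + np.exp((v - 10.0) / 30.0))
    GKr = 0.046 * g[4]
    if ct == 1:
        GKr *= 1.3
    elif ct == 2:
        GKr *= 0.8
    IKr = GKr * np.sqrt(ko / 5.4) * xr * rkr * (v - EK)

    # --- I_Ks ---
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    inf[32] = xs1ss; tau[32] = txs1
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    inf[33] = xs1ss; tau[33] = txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * g[5]
    if ct == 1:
        GKs *= 1.4
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # --- I_K1 ---
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * ko + 144.59)
                                / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36)
                    + np.exp((v + 236.8) / 69.33))
    inf[34] = xk1ss; tau[34] = txk1
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * ko) / 9.493))
    GK1 = 0.1908 * g[6]
    if ct == 1:
        GK1 *= 1.2
    elif ct == 2:
        GK1 *= 1.3
    IK1 = GK1 * np.sqrt(ko) * rk1 * xk1 * (v - EK)

    # --- I_NaCa (myoplasmic and subspace components) ---
    kna1 = 15.0; kna2 = 5.0; kna3 = 88.12
    kasymm = 12.5; wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
    kcaon = 1.5e6; kcaoff = 5.0e3
    qna = 0.5224; qca = 0.1670
    hca = np.exp(qca * v * F / (R * T))
    hna = np.exp(qna * v * F / (R * T))
    Gncx = 0.0008 * g[7]
    if ct == 1:
        Gncx *= 1.1
    elif ct == 2:
        Gncx *= 1.4
    zca = 2.0
    zna = 1.0
    INaCa = 0.0
    for comp in range(2):
        if comp == 0:
            na = nai; ca = cai; wt = 0.8
        else:
            na = nass; ca = cass; wt = 0.2
        h1 = 1.0 + na / kna3 * (1.0 + hna)
        h2 = (na * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + na / kna1 * (1.0 + na / kna2)
        h5 = na * na / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
        h8 = nao / (kna3 * hna * h7)
        h9 = 1.0 / h7
        h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
        h11 = nao * nao / (h10 * kna1 * kna2)
        h12 = 1.0 / h10
        k1 = h12 * cao * kcaon
        k2 = kcaoff
        k3p = h9 * wca
        k3pp = h8 * wnaca
        k3 = k3p + k3pp
        k4p = h3 * wca / hca
        k4pp = h2 * wnaca
        k4 = k4p + k4pp
        k5 = kcaoff
        k6 = h6 * ca * kcaon
        k7 = h5 * h2 * wna
        k8 = h8 * h11 * wna
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        KmCaAct = 150.0e-6
        allo = 1.0 / (1.0 + (KmCaAct / ca) ** 2)
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        comp_cur = wt * Gncx * allo * (zna * JncxNa + zca * JncxCa)
        if comp == 0:
            INaCa_i = comp_cur
        else:
            INaCa_ss = comp_cur
    INaCa = INaCa_i + INaCa_ss

    # --- I_NaK ---
    k1p = 949.5; k1m = 182.4; k2p = 687.2; k2m = 39.4
    k3p_ = 1899.0; k3m = 79300.0; k4p_ = 639.0; k4m = 40.0
    Knai0 = 9.073; Knao0 = 27.78; delta = -0.1550
    Knai = Knai0 * np.exp(delta * v * F / (3.0 * R * T))
    Knao = Knao0 * np.exp((1.0 - delta) * v * F / (3.0 * R * T))
    Kki = 0.5; Kko = 0.3582
    MgADP = 0.05; MgATP = 9.8; Kmgatp = 1.698e-7
    H = 1.0e-7; eP = 4.2; Khp = 1.698e-7; Knap = 224.0; Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) \
        / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3) \
        / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0)
    a3 = (k3p_ * (ko / Kko) ** 2) \
        / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p_ * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) \
        / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0 * g[8]
    if ct == 1:
        Pnak *= 0.9
    elif ct == 2:
        Pnak *= 0.7
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # --- background and pump currents ---
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    if ct == 1:
        GKb *= 0.6
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * vffrt * (nai * ex1 - nao) / (ex1 - 1.0)
    PCab = 2.5e-8
    ICab = PCab * 4.0 * vffrt * (cai * ex2 - 0.341 * cao) / (ex2 - 1.0)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    Iion = INa + INaL + ICaL + ICaNa + ICaK + Ito + IKr + IKs + IK1 \
        + INaCa + INaK + INab + ICab + IKb + IpCa

    cur[0] = INa; cur[1] = INaL; cur[2] = ICaL; cur[3] = ICaNa
    cur[4] = ICaK; cur[5] = Ito; cur[6] = IKr; cur[7] = IKs
    cur[8] = IK1; cur[9] = INaCa; cur[10] = INaK; cur[11] = INab
    cur[12] = ICab; cur[13] = IKb; cur[14] = IpCa; cur[15] = Iion

    # --- SR calcium fluxes ---
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if ct == 2:
        Jrel_inf *= 1.7
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    inf[35] = Jrel_inf; tau[35] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if ct == 2:
        Jrel_infp *= 1.7
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    inf[36] = Jrel_infp; tau[36] = tau_relp
    Jrel = (1.0 - fphos) * Jrelnp + fphos * Jrelp

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    if ct == 1:
        Jupnp *= 1.3
        Jupp *= 1.3
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fphos) * Jupnp + fphos * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # --- concentration balances ---
    dy[1] = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) \
        * Acap / (F * vmyo) + JdiffNa * vss / vmyo
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * Acap / (F * vss) - JdiffNa
    dy[3] = -(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK) \
        * Acap / (F * vmyo) + JdiffK * vss / vmyo
    dy[4] = -ICaK * Acap / (F * vss) - JdiffK
    cmdnmax = 0.05
    if ct == 1:
        cmdnmax *= 1.3
    kmcmdn = 0.00238; trpnmax = 0.07; kmtrpn = 0.0005
    BSRmax = 0.047; KmBSR = 0.00087
    BSLmax = 1.124; KmBSL = 0.0087
    csqnmax = 10.0; kmcsqn = 0.8
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * Acap / (2.0 * F * vmyo)
                    - Jup * vnsr / vmyo + Jdiff * vss / vmyo)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dy[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * Acap / (2.0 * F * vss)
                     + Jrel * vjsr / vss - Jdiff)
    dy[7] = Jup - Jtr * vjsr / vnsr
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = Bcajsr * (Jtr - Jrel)

    # membrane potential
    dy[0] = -(Iion + istim)  # per Cm = 1 µF/cm²; scaled by caller if needed


@njit(cache=True)
def _ord_step(y, ct, g, istim, dt, dv_extra, inf, tau, dy, cur):
    """Advance one state vector by dt (Rush–Larsen + forward Euler).

    dv_extra is an additive membrane-potential increment (mV) used by the
    tissue solver to inject the diffusion term.
    """
    _ord_eval(y, ct, g, istim, inf, tau, dy, cur)
    for k in range(_GATE_LO, _GATE_HI):
        y[k] = inf[k] + (y[k] - inf[k]) * np.exp(-dt / tau[k])
    y[1] += dt * dy[1]
    y[2] += dt * dy[2]
    y[3] += dt * dy[3]
    y[4] += dt * dy[4]
    y[5] += dt * dy[5]
    y[6] += dt * dy[6]
    y[7] += dt * dy[7]
    y[8] += dt * dy[8]
    y[37] += dt * dy[37]
    y[0] += dt * dy[0] + dv_extra


@njit(cache=True)
def _run_cell(y, ct, g, dt, nsteps, stims, rec_stride, v_out, cur_out,
              rec_currents):
    """Integrate a single cell for nsteps.

    stims: (n, 3) array of (start_ms, duration_ms, amplitude).
    Records Vm (and optionally currents) every rec_stride steps, sampling
    the pre-step state.  Returns -1 on success or the failing step index.
    """
    inf = np.empty(N_STATE)
    tau = np.empty(N_STATE)
    dy = np.empty(N_STATE)
    cur = np.empty(16)
    nrec = v_out.shape[0]
    for i in range(nsteps):
        t = i * dt
        istim = 0.0
        for s in range(stims.shape[0]):
            if stims[s, 0] <= t < stims[s, 0] + stims[s, 1]:
                istim += stims[s, 2]
        if i % rec_stride == 0:
            r = i // rec_stride
            if r < nrec:
                v_out[r] = y[0]
                if rec_currents:
                    _ord_eval(y, ct, g, istim, inf, tau, dy, cur)
                    for c in range(16):
                        cur_out[r, c] = cur[c]
        _ord_step(y, ct, g, istim, dt, 0.0, inf, tau, dy, cur)
        if not np.isfinite(y[0]):
            return i
    return -1


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------

_REST_STATES = None


def _load_rest_states():
    global _REST_STATES
    if _REST_STATES is None:
        with resources.files("cardiosim.data").joinpath(
                "ord_rest_states.json").open() as fh:
            _REST_STATES = json.load(fh)
    return _REST_STATES


def init_state(cell_type) -> np.ndarray:
    """Resting state vector for a cell type.

    The values are quiescent equilibria of this model (ORd with the TNNP06
    fast Na⁺ current), precomputed by integrating each unstimulated cell to
    rest and shipped with the package; the TNNP06 gates sit at their
    steady state for the resting potential.
    """
    try:
        ct = CellType(cell_type) if not isinstance(cell_type, str) \
            else CellType[cell_type.upper()]
    except (ValueError, KeyError):
        raise ValueError(f"unknown cell type: {cell_type!r}")
    states = _load_rest_states()
    return np.array(states[ct.name], dtype=float)


def compute_currents(state, params: CellParams | None = None,
                     factors=None) -> dict:
    """All transmembrane currents (µA/µF) at a fixed state.

    Each scalable current equals its unscaled value times its channel
    factor; ``I_ion`` is the sum of every constituent current.
    """
    if params is None:
        params = CellParams()
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have length {N_STATE}")
    g = params.multipliers(factors)
    inf = np.empty(N_STATE)
    tau = np.empty(N_STATE)
    dy = np.empty(N_STATE)
    cur = np.empty(16)
    _ord_eval(y, int(params.cell_type), g, 0.0, inf, tau, dy, cur)
    return dict(zip(CURRENT_NAMES, cur))


class NumericalBlowup(RuntimeError):
    """Non-finite state detected during integration."""

    def __init__(self, step: int, where: str = "cell"):
        self.step = step
        super().__init__(f"non-finite state at step {step} ({where})")


def step_cell(state, params: CellParams | None = None, factors=None,
              i_stim: float = 0.0, dt: float = 0.005) -> np.ndarray:
    """Advance the full state by one step of dt (ms); returns a new vector."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params is None:
        params = CellParams()
    y = np.array(state, dtype=float)
    g = params.multipliers(factors)
    inf = np.empty(N_STATE)
    tau = np.empty(N_STATE)
    dy = np.empty(N_STATE)
    cur = np.empty(16)
    _ord_step(y, int(params.cell_type), g, i_stim / params.cm, dt, 0.0,
              inf, tau, dy, cur)
    if not np.isfinite(y[0]):
        raise NumericalBlowup(0)
    return y


def run_unstimulated(params: CellParams | None = None, factors=None,
                     duration: float = 10000.0, dt: float = 0.005,
                     y0=None, rec_dt: float = 10.0) -> tuple[Trace, np.ndarray]:
    """Integrate a quiescent cell; returns (trace, final state)."""
    if params is None:
        params = CellParams()
    y = np.array(init_state(params.cell_type) if y0 is None else y0,
                 dtype=float)
    g = params.multipliers(factors)
    nsteps = int(round(duration / dt))
    stride = max(1, int(round(rec_dt / dt)))
    nrec = (nsteps + stride - 1) // stride
    v_out = np.empty(nrec)
    cur_out = np.empty((1, 16))
    bad = _run_cell(y, int(params.cell_type), g, dt, nsteps,
                    np.zeros((0, 3)), stride, v_out, cur_out, False)
    if bad >= 0:
        raise NumericalBlowup(bad)
    t = np.arange(nrec) * stride * dt
    return Trace(t=t, vm=v_out, dt=dt), y


def pace_cell(params: CellParams | None = None, factors=None,
              bcl: float = 1000.0, n_beats: int = 100, dt: float = 0.005,
              rec_dt: float = 0.1, y0=None, record_all: bool = False,
              record_currents: bool = False) -> Trace:
    """Pace a cell at a fixed BCL and return the recorded trace.

    By default only the final beat is returned (``record_all=True`` keeps
    every beat).  ``trace.steady`` reports whether the consecutive-beat
    criterion |ΔAPD90| < 1 ms held over the last two beats;
    ``trace.meta['final_state']`` holds the end-of-run state vector.
    """
    if params is None:
        params = CellParams()
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if bcl <= params.stim_duration:
        raise ValueError("BCL must exceed the stimulus duration")
    y = np.array(init_state(params.cell_type) if y0 is None else y0,
                 dtype=float)
    g = params.multipliers(factors)
    stride = max(1, int(round(rec_dt / dt)))

    stims = np.empty((n_beats, 3))
    for b in range(n_beats):
        stims[b] = (b * bcl, params.stim_duration,
                    params.stim_amplitude / params.cm)

    nsteps = int(round(n_beats * bcl / dt))
    nrec = (nsteps + stride - 1) // stride
    keep_from = 0 if record_all else int(round((n_beats - 1) * bcl / dt)) // stride
    v_out = np.empty(nrec)
    cur_out = np.empty((nrec if record_currents else 1, 16))
    bad = _run_cell(y, int(params.cell_type), g, dt, nsteps, stims, stride,
                    v_out, cur_out, record_currents)
    if bad >= 0:
        raise NumericalBlowup(bad)
    t_full = np.arange(nrec) * stride * dt

    # per-beat APD90 for the steady-state report
    from . import biomarkers
    apds = []
    rec_per_beat = int(round(bcl / (stride * dt)))
    for b in range(n_beats):
        lo, hi = b * rec_per_beat, min((b + 1) * rec_per_beat, nrec)
        try:
            apds.append(biomarkers.apd(
                Trace(t=t_full[lo:hi], vm=v_out[lo:hi]), level=90))
        except biomarkers.BiomarkerError:
            apds.append(np.nan)
    steady = (len(apds) >= 2 and np.isfinite(apds[-1])
              and np.isfinite(apds[-2]) and abs(apds[-1] - apds[-2]) < 1.0)

    sl = slice(keep_from, nrec)
    trace = Trace(
        t=t_full[sl] - t_full[keep_from], vm=v_out[sl],
        currents=(dict(zip(CURRENT_NAMES, cur_out[sl].T))
                  if record_currents else None),
        bcl=bcl, n_beats=n_beats, dt=dt, steady=steady, apd_history=apds,
        stim_times=stims[:, 0] - t_full[keep_from],
        meta={"final_state": y, "cell_type": params.cell_type.name,
              "factors": None if factors is None
              else list(_factors_to_array(factors))},
    )
    return trace


def equilibrate_rest(cell_type, duration: float = 800000.0,
                     dt: float = 0.01) -> np.ndarray:
    """Integrate an unstimulated cell from generic initial conditions to
    its quiescent equilibrium (used to regenerate the shipped rest states)."""
    y = _generic_initial_state(cell_type)
    params = CellParams(cell_type=CellType(cell_type) if not isinstance(
        cell_type, str) else CellType[cell_type.upper()])
    g = params.multipliers(None)
    v_out = np.empty(1)
    cur_out = np.empty((1, 16))
    nsteps = int(round(duration / dt))
    bad = _run_cell(y, int(params.cell_type), g, dt, nsteps,
                    np.zeros((0, 3)), nsteps + 1, v_out, cur_out, False)
    if bad >= 0:
        raise NumericalBlowup(bad)
    return y


def _generic_initial_state(cell_type) -> np.ndarray:
    """Generic pre-equilibration initial conditions (resting-ballpark
    voltage, closed activation gates, open inactivation gates)."""
    y = np.zeros(N_STATE)
    v0 = -87.0
    y[0] = v0
    y[1] = 7.0; y[2] = 7.0        # nai, nass
    y[3] = 145.0; y[4] = 145.0    # ki, kss
    y[5] = 1.0e-4; y[6] = 1.0e-4  # cai, cass
    y[7] = 1.2; y[8] = 1.2        # cansr, cajsr
    # TNNP06 gates at steady state for v0
    y[9] = 1.0 / (1.0 + np.exp((-56.86 - v0) / 9.03)) ** 2
    y[10] = 1.0 / (1.0 + np.exp((v0 + 71.55) / 7.43)) ** 2
    y[11] = y[10]
    for idx, name in enumerate(STATE_NAMES):
        if name in ("hL", "hLp", "iF", "iS", "iFp", "iSp", "ff", "fs",
                    "fcaf", "fcas", "jca", "ffp", "fcafp", "xk1"):
            y[idx] = 1.0
    return y
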