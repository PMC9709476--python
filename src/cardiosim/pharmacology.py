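"""Hill-equation ion-channel pharmacology.

Drug–channel interactions follow simple pore-block theory: the blocked
fraction of a current at drug concentration [D] is

    theta = 1 / (1 + (IC50/[D])^nH)

so the conductance that remains is f = 1 - theta.  Channel activators are
described by the complementary sigmoid

    f = 1 + (Act_max - 1) / (1 + (EC50/[D])^nH)

which runs from 1 at zero dose to the maximal fold-activation Act_max.
Per-drug factor sets act multiplicatively on the nine scalable currents of
the cell model (I_ion -> f_ion * I_ion) and compose multiplicatively with
disease-remodeling factor sets.

The bundled drug library covers seven multi-channel blockers (ranolazine,
amiodarone, verapamil, nifedipine, quinidine, vanoxerine, bepridil) and
five I_Kr activators (HW-0168, KB130015, ICA-105574, NS1643, NS3623),
each with per-channel Hill parameters, provenance notes and dose plans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .ord import CHANNELS

__all__ = [
    "HillBlock", "HillActivation", "DrugSpec", "ConductanceFactors",
    "DoseResponsePoints", "block_fraction", "remaining_fraction",
    "activation_factor", "drug_factors", "compose_factors", "fit_hill",
    "load_drug_library", "load_remodeling", "FitResult",
]


@dataclass(frozen=True)
class HillBlock:
    """Pore-block dose–response parameters."""

    ic50: float   # µM
    nh: float     # Hill coefficient

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")
        if self.nh <= 0:
            raise ValueError("Hill coefficient must be positive")


@dataclass(frozen=True)
class HillActivation:
    """Channel-activation dose–response parameters."""

    ec50: float      # µM
    nh: float
    act_max: float   # maximal fold-activation, >= 1

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.nh <= 0:
            raise ValueError("Hill coefficient must be positive")
        if self.act_max < 1:
            raise ValueError("Act_max must be >= 1")


@dataclass(frozen=True)
class DrugEntry:
    mode: str                      # "block" | "activate"
    hill: HillBlock | HillActivation
    note: str = ""                 # species / provenance

    def __post_init__(self):
        if self.mode not in ("block", "activate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        want = HillBlock if self.mode == "block" else HillActivation
        if not isinstance(self.hill, want):
            raise TypeError(f"{self.mode} entry needs {want.__name__}")


@dataclass(frozen=True)
class DrugSpec:
    """Per-channel Hill records for one compound; channels absent from
    ``entries`` are unaffected."""

    name: str
    entries: dict = field(default_factory=dict)  # channel id -> DrugEntry
    doses: dict = field(default_factory=dict)    # plan name -> µM

    def __post_init__(self):
        for ch in self.entries:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel id {ch!r}")


class ConductanceFactors(dict):
    """Map channel id -> multiplicative factor (>= 0); missing channels
    default to 1.0."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for ch, f in self.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel id {ch!r}")
            if f < 0:
                raise ValueError(f"factor for {ch} must be >= 0")

    def __missing__(self, key):
        if key not in CHANNELS:
            raise KeyError(key)
        return 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.get(ch, 1.0) for ch in CHANNELS])

    @classmethod
    def ones(cls) -> "ConductanceFactors":
        return cls()


@dataclass(frozen=True)
class DoseResponsePoints:
    """Experimental or synthetic (dose µM, response fraction) pairs."""

    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.shape != r.shape or d.ndim != 1:
            raise ValueError("doses and responses must be equal-length 1D")
        if np.any(d <= 0) or len(np.unique(d)) != len(d):
            raise ValueError("doses must be positive and distinct")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "responses", r)

    def __len__(self):
        return len(self.doses)


# ----------------------------------------------------------------------
# evaluators
# ----------------------------------------------------------------------

def block_fraction(dose, hill: HillBlock):
    """Blocked fraction theta in [0, 1); theta(0) = 0, theta(IC50) = 1/2."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    with np.errstate(divide="ignore"):
        theta = np.where(dose > 0,
                         1.0 / (1.0 + (hill.ic50 / np.where(dose > 0, dose, 1.0))
                                ** hill.nh),
                         0.0)
    return float(theta) if theta.ndim == 0 else theta


def remaining_fraction(dose, hill: HillBlock):
    """Remaining conductance f = 1 - theta = 1/(1 + (dose/IC50)^nH)."""
    return 1.0 - block_fraction(dose, hill)


def activation_factor(dose, hill: HillActivation):
    """Fold-activation f in [1, Act_max]; f(0) = 1, f(EC50) = 1 + span/2."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    f = np.where(dose > 0,
                 1.0 + (hill.act_max - 1.0)
                 / (1.0 + (hill.ec50 / np.where(dose > 0, dose, 1.0))
                    ** hill.nh),
                 1.0)
    return float(f) if f.ndim == 0 else f


def drug_factors(drug: DrugSpec, dose: float) -> ConductanceFactors:
    """Evaluate every channel entry of a drug at a dose; untouched channels
    get 1.0."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    out = ConductanceFactors()
    for ch, entry in drug.entries.items():
        if entry.mode == "block":
            out[ch] = remaining_fraction(dose, entry.hill)
        else:
            out[ch] = activation_factor(dose, entry.hill)
    return out


def compose_factors(*factor_sets) -> ConductanceFactors:
    """Per-channel product of factor sets (commutative, associative);
    used to stack disease remodeling and drugs."""
    if not factor_sets:
        raise ValueError("need at least one factor set")
    out = ConductanceFactors()
    for fs in factor_sets:
        for ch in fs:
            out[ch] = out.get(ch, 1.0) * fs[ch]
    return out


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    hill: HillBlock | HillActivation
    residual_norm: float
    n_points: int


def fit_hill(points: DoseResponsePoints, mode: str = "block") -> FitResult:
    """Least-squares Hill fit of a dose–response point set.

    Block mode fits the blocked fraction theta(dose); activation mode fits
    the fold-activation f(dose).  Initialization is deterministic: IC50/EC50
    at the geometric mean of the dose range, nH = 1, and Act_max at the
    maximum observed response.
    """
    d = points.doses
    r = points.responses
    if np.allclose(r, r[0]):
        raise ValueError("degenerate data: all responses equal")
    gm = float(np.exp(np.mean(np.log(d))))
    if mode == "block":
        if len(points) < 3:
            raise ValueError("block fit needs >= 3 points (2 parameters)")

        def model(x, ic50, nh):
            return 1.0 / (1.0 + (ic50 / x) ** nh)

        p0 = (gm, 1.0)
        bounds = ([1e-12, 1e-6], [np.inf, 50.0])
    elif mode == "activate":
        if len(points) < 4:
            raise ValueError("activation fit needs >= 4 points (3 parameters)")

        def model(x, ec50, nh, act_max):
            return 1.0 + (act_max - 1.0) / (1.0 + (ec50 / x) ** nh)

        p0 = (gm, 1.0, max(float(np.max(r)), 1.0 + 1e-6))
        bounds = ([1e-12, 1e-6, 1.0], [np.inf, 50.0, np.inf])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    try:
        popt, _ = curve_fit(model, d, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(model(d, *popt) - r))
    hill = (HillBlock(*popt) if mode == "block"
            else HillActivation(*popt))
    return FitResult(hill=hill, residual_norm=resid, n_points=len(points))


# ----------------------------------------------------------------------
# bundled library
# ----------------------------------------------------------------------

def _parse_drug(name: str, raw: dict) -> DrugSpec:
    entries = {}
    for ch, e in raw.get("channels", {}).items():
        mode = e["mode"]
        if mode == "block":
            hill = HillBlock(ic50=float(e["ic50"]), nh=float(e["nh"]))
        else:
            hill = HillActivation(ec50=float(e["ec50"]), nh=float(e["nh"]),
                                  act_max=float(e["act_max"]))
        entries[ch] = DrugEntry(mode=mode, hill=hill, note=e.get("note", ""))
    doses = {k: float(v) for k, v in raw.get("doses", {}).items()}
    return DrugSpec(name=name, entries=entries, doses=doses)


def load_drug_library(path=None) -> dict:
    """Bundled drug library: map name -> DrugSpec (with dose plans)."""
    if path is None:
        with resources.files("cardiosim.data").joinpath("drugs.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "drugs" not in raw:
        raise ValueError("malformed drug library file: missing 'drugs'")
    return {name: _parse_drug(name, spec)
            for name, spec in raw["drugs"].items()}


def save_drug_library(library: dict, path) -> None:
    """Write a drug library back to YAML (round-trips with the loader)."""
    out = {"drugs": {}}
    for name, spec in library.items():
        channels = {}
        for ch, e in spec.entries.items():
            if e.mode == "block":
                channels[ch] = {"mode": "block", "ic50": e.hill.ic50,
                                "nh": e.hill.nh, "note": e.note}
            else:
                channels[ch] = {"mode": "activate", "ec50": e.hill.ec50,
                                "nh": e.hill.nh, "act_max": e.hill.act_max,
                                "note": e.note}
        out["drugs"][name] = {"channels": channels, "doses": spec.doses}
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


def load_remodeling(condition: str, path=None) -> tuple[ConductanceFactors, dict]:
    """Disease-remodeling factor set for a named condition.

    Returns (factors, metadata).  The bundled file ships clearly-flagged
    synthetic placeholder magnitudes (see its ``provenance`` fields); users
    with measured remodeling data should point ``path`` at their own file.
    """
    if path is None:
        with resources.files("cardiosim.data").joinpath(
                "remodeling_placeholder.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if condition not in raw:
        raise KeyError(f"unknown condition {condition!r}; "
                       f"have {sorted(raw)}")
    entry = raw[condition]
    factors = ConductanceFactors(
        {ch: float(v) for ch, v in entry.get("factors", {}).items()})
    meta = {k: v for k, v in entry.items() if k != "factors"}
    return factors, meta
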