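"""Run configuration: schema-validated structured-text (YAML) configs,
scenario execution and provenance records.

A scenario names a condition stack ("healthy", "HF + CO + ranolazine", …)
operationally: zero or more remodeling factor sets composed with an
optional drug at a dose, applied either to a single paced cell or to a 1D
strand with a pseudo-ECG readout.  Every output carries the SHA-256 hash
of the canonical config so results can be re-derived bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__, biomarkers, ord
from .pharmacology import (ConductanceFactors, compose_factors,
                           drug_factors, load_drug_library, load_remodeling)

__all__ = ["RunConfig", "load_config", "save_config", "config_hash",
           "run_scenario", "ConfigError"]


class ConfigError(ValueError):
    pass


class DrugDose(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    dose: float = Field(ge=0.0)   # µM


class CellSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cell_type: Literal["ENDO", "MID", "EPI"] = "ENDO"
    bcl: float = Field(default=1000.0, gt=0)
    n_beats: int = Field(default=10, ge=1)
    dt: float = Field(default=0.005, gt=0)


class StrandSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    transmural: bool = True
    D: float = Field(default=0.127, gt=0)
    bcl: float = Field(default=1000.0, gt=0)
    n_beats: int = Field(default=5, ge=1)
    dt: float = Field(default=0.005, gt=0)
    cell_prebeats: int = Field(default=100, ge=0)
    electrode_mm: Optional[float] = None
    radius_mm: float = 1.1


class RunConfig(BaseModel):
    """Validated scenario configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    scenario: str = "healthy"
    mode: Literal["cell", "strand"] = "cell"
    conditions: list[str] = Field(default_factory=list)
    drug: Optional[DrugDose] = None
    cell: CellSection = Field(default_factory=CellSection)
    strand: StrandSection = Field(default_factory=StrandSection)
    remodeling_file: Optional[str] = None
    seed: int = 0
    outdir: str = "runs"


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; raises ConfigError naming the
    offending field on schema violations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"config error at '{loc}': {first['msg']}") from exc


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def build_factors(cfg: RunConfig) -> ConductanceFactors:
    sets = []
    for cond in cfg.conditions:
        fac, _ = load_remodeling(cond, path=cfg.remodeling_file)
        sets.append(fac)
    if cfg.drug is not None:
        lib = load_drug_library()
        if cfg.drug.name not in lib:
            raise ConfigError(f"unknown drug {cfg.drug.name!r}")
        sets.append(drug_factors(lib[cfg.drug.name], cfg.drug.dose))
    return compose_factors(*sets) if sets else ConductanceFactors()


def run_scenario(cfg: RunConfig, write: bool = True) -> dict:
    """Execute the configured pipeline and return the summary dict.

    cell mode: pace one myocyte, report APD90 and the EAD pattern.
    strand mode: simulate the strand, compute the pseudo-ECG, report QT,
    T-wave amplitude and CV.
    """
    from . import strand as strand_mod
    from .io import ecg_to_csv, strand_to_hdf5, trace_to_csv

    factors = build_factors(cfg)
    outdir = Path(cfg.outdir) / cfg.scenario.replace(" ", "_")
    summary: dict = {
        "scenario": cfg.scenario,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "factors": dict(factors),
    }
    if cfg.mode == "cell":
        params = ord.CellParams(
            cell_type=ord.CellType[cfg.cell.cell_type])
        tr = ord.pace_cell(params, factors=factors, bcl=cfg.cell.bcl,
                           n_beats=cfg.cell.n_beats, dt=cfg.cell.dt,
                           record_all=True)
        t0 = tr.stim_times[-1]
        sel = tr.t >= t0
        try:
            apd90 = biomarkers.apd(ord.Trace(t=tr.t[sel], vm=tr.vm[sel]))
        except biomarkers.BiomarkerError:
            apd90 = None
        rep = biomarkers.detect_eads(tr)
        summary.update({
            "apd90_ms": apd90,
            "ead_counts": rep.counts,
            "ead_pattern": rep.pattern,
            "steady": tr.steady,
        })
        if write:
            outdir.mkdir(parents=True, exist_ok=True)
            trace_to_csv(tr, outdir / "trace.csv")
    else:
        s = cfg.strand
        if s.transmural:
            scfg = strand_mod.build_transmural_strand(
                D=s.D, bcl=s.bcl, n_beats=s.n_beats, dt=s.dt,
                cell_prebeats=s.cell_prebeats)
        else:
            scfg = strand_mod.build_homogeneous_strand(
                D=s.D, bcl=s.bcl, n_beats=s.n_beats, dt=s.dt,
                cell_prebeats=s.cell_prebeats)
        scfg.node_factors = scfg.node_factors * factors.as_array()[None, :]
        tr = strand_mod.simulate_strand(scfg)
        ecg = biomarkers.pseudo_ecg(tr, electrode_mm=s.electrode_mm,
                                    radius_mm=s.radius_mm)
        try:
            qt = biomarkers.measure_qt(ecg)
        except biomarkers.BiomarkerError as exc:
            qt = {"error": str(exc)}
        try:
            cv = strand_mod.measure_cv(tr)
        except strand_mod.ConductionBlock as exc:
            cv = None
        summary.update({"qt": qt, "cv_cm_s": cv})
        if write:
            outdir.mkdir(parents=True, exist_ok=True)
            strand_to_hdf5(tr, outdir / "strand.h5")
            ecg_to_csv(ecg, outdir / "ecg.csv")
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=1)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
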