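# cardiosim

Simulation toolkit for assessing how multi-channel drugs reshape human
ventricular electrophysiology, from single myocytes to a 1D transmural
tissue strand with a pseudo-ECG readout.  It was built for the study of
drug therapy in hearts whose ion channels are remodeled by disease or by
toxic exposures such as carbon monoxide (which enhances the late Na⁺
current and depresses I_Na, I_CaL, I_K1 and I_Kr), where the question is
whether a candidate compound shortens or further prolongs repolarization
once all of its channel affinities act at once.

## What it computes

**Cell model.** The O'Hara–Rudy dynamics (ORd) human ventricular myocyte
for ENDO, MID and EPI cell types, with the fast sodium current replaced by
the ten Tusscher (TNNP06) formulation so that coupled tissue conducts at
physiological velocity:

    dVm/dt = -(I_ion + I_stim) / Cm

**Pharmacology.** Simple pore-block theory.  A drug at concentration [D]
blocks the fraction

    θ = 1 / (1 + (IC50/[D])^nH)

of a current, so the current is scaled by f = 1 − θ; channel activators
scale by f = 1 + (Act_max − 1)/(1 + (EC50/[D])^nH).  Per-drug factor sets
multiply the nine major conductances (I_Na, I_NaL, I_CaL, I_to, I_Kr,
I_Ks, I_K1, I_NaCa, I_NaK) and compose multiplicatively with
disease-remodeling factor sets.  A library of 12 compounds (7
multi-channel blockers, 5 I_Kr activators) with per-channel Hill
parameters and dose plans ships with the package, along with Hill-curve
fitting for new dose–response data.

**Tissue.** A monodomain cable, dVm/dt = D ∂²Vm/∂x² − I_ion/Cm, with
no-flux boundaries; the default strand is 15 mm, 100 nodes (dx = 0.15 mm),
25:35:40 ENDO:MID:EPI, D = 0.127 mm²/ms, which conducts a planar wave at
~70 cm/s.  The unipolar pseudo-ECG is computed from the spatial gradient
of Vm,

    φ_e(x') = (a²/4) ∫ (−∇Vm) · ∇(1/r) dx

**Biomarkers and protocols.** APD90, EAD detection with beat-pattern
labels (2:1, 1:1), QT interval and T-wave amplitude from the pseudo-ECG,
transmural dispersion; CV dynamic restitution, S1–S2 vulnerable-window
scans, the critical number of EAD-prone cells needed to fire a propagated
ectopic beat (source–sink analysis), and populations of models with
normally distributed conductance scaling (mean 1.0, sd 0.2).

## Worked example

Ranolazine at its therapeutic 10 µM, evaluated through the drug library:

```python
>>> from cardiosim import load_drug_library, drug_factors
>>> fac = drug_factors(load_drug_library()["ranolazine"], 10.0)
>>> {ch: round(f, 3) for ch, f in sorted(fac.items())}
{'I_CaL': 0.967, 'I_Kr': 0.545, 'I_Na': 0.983, 'I_NaCa': 0.963, 'I_NaL': 0.384}
```

The drug blocks 61.6% of the late Na⁺ current (its intended target) but
also 45.5% of I_Kr — which is why, on a cell whose repolarization reserve
is already reduced, it prolongs rather than shortens the action potential:

```python
>>> from cardiosim import CellParams, CellType, pace_cell, compose_factors
>>> from cardiosim.pharmacology import load_remodeling
>>> from cardiosim.biomarkers import apd
>>> co, _ = load_remodeling("CO")     # flagged placeholder remodeling set
>>> for name, f in [("healthy", None), ("healthy+CO", co),
...                 ("healthy+CO+RAN", compose_factors(co, fac))]:
...     print(name, round(apd(pace_cell(CellParams(), factors=f,
...                                     bcl=1000, n_beats=10))))
healthy 294
healthy+CO 507
healthy+CO+RAN 577
```

APD90 in ms: the CO-like remodeling prolongs the ENDO action potential
and ranolazine prolongs it further instead of rescuing it.  The same
stack runs at tissue level (`cardiosim run --config …`, mode `strand`)
and reports QT and T-wave amplitude from the pseudo-ECG.

From the shell, an EAD-prone MID cell under the composed placeholder
heart-failure + CO condition:

```bash
$ cardiosim simulate-cell --cell-type MID --beats 4 --condition HF+CO
{"apd90_ms": 193.8, "ead_counts": [1, 0, 1, 0], "ead_pattern": "2:1"}
```

(2:1 alternating early afterdepolarizations; the short final APD is the
post-EAD alternans beat.)

Disease-remodeling magnitudes are consumed as user-editable YAML; the
bundled `data/remodeling_placeholder.yaml` contains clearly flagged
synthetic stand-ins, so all disease-condition outputs above illustrate
the machinery, not measured biology.

## Layout

| module | contents |
| --- | --- |
| `cardiosim.ord` | ORd+TNNP06 myocyte, Rush–Larsen/Euler integrator, pacing |
| `cardiosim.pharmacology` | Hill evaluators, fitting, drug library, factor algebra |
| `cardiosim.strand` | monodomain 1D cable, CV measurement |
| `cardiosim.biomarkers` | APD, EAD, pseudo-ECG, QT, dispersion |
| `cardiosim.protocols` | restitution, vulnerable window, critical mass, populations |
| `cardiosim.synthetic` | fixtures with known ground truth |
| `cardiosim.surrogate` | fast two-variable excitable cell for protocol logic |
| `cardiosim.config` / `cardiosim.cli` | YAML scenarios, provenance, `cardiosim` CLI |

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
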