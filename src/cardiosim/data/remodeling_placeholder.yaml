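# SYNTHETIC PLACEHOLDER remodeling factor sets.
#
# These magnitudes are NOT measured values: they are conservative,
# package-authored stand-ins whose direction of effect matches the
# qualitative electrophysiology of each condition (CO exposure enhances
# I_NaL and depresses I_Na, I_CaL, I_K1 and I_Kr; heart failure reduces
# the repolarization reserve and potassium currents).  Replace them with
# measured remodeling magnitudes before drawing quantitative conclusions.
#
# Magnitudes were chosen so that the composed HF+CO MID cell reproduces
# the qualitative phenomenology of the modeled disease state (prolonged
# APD with early afterdepolarizations) while HF alone stays EAD-free.
CO:
  provenance: "PLACEHOLDER (synthetic) — replace with measured CO/CORM-2 remodeling"
  factors:
    I_Na: 0.9
    I_NaL: 2.0
    I_CaL: 0.95
    I_K1: 0.9
    I_Kr: 0.55
HF:
  provenance: "PLACEHOLDER (synthetic) — replace with measured heart-failure remodeling"
  factors:
    I_NaL: 1.8
    I_to: 0.4
    I_Ks: 0.6
    I_K1: 0.75
    I_NaK: 0.7
    I_NaCa: 1.65
HF+CO:
  provenance: "PLACEHOLDER (synthetic) — product of the HF and CO placeholder sets"
  compose: [HF, CO]
  factors:
    I_Na: 0.9
    I_NaL: 3.6
    I_CaL: 0.95
    I_to: 0.4
    I_Ks: 0.6
    I_K1: 0.675
    I_Kr: 0.55
    I_NaK: 0.7
    I_NaCa: 1.65
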