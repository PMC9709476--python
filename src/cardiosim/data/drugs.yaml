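# Bundled drug library: per-channel Hill parameters and dose plans.
#
# Blockers carry (ic50 [µM], nh); activators carry (ec50 [µM], nh, act_max).
# "note" records the expression system / species of the source measurement.
# Dose plans: "therapeutic" is the dose used in the worked analyses;
# high/medium/low are the C_max-based exploration doses for the six
# multi-channel blockers.
drugs:
  ranolazine:
    channels:
      I_Na:   {mode: block, ic50: 53.6,  nh: 2.4,  note: "HEK 293"}
      I_NaL:  {mode: block, ic50: 6.23,  nh: 1.0,  note: "canine"}
      I_NaCa: {mode: block, ic50: 91.0,  nh: 1.48, note: "canine"}
      I_CaL:  {mode: block, ic50: 296.0, nh: 1.0,  note: "canine"}
      I_Kr:   {mode: block, ic50: 12.0,  nh: 1.0,  note: "HEK 293"}
    doses: {therapeutic: 10.0}
  hw-0168:
    channels:
      I_Kr:   {mode: activate, ec50: 0.41, nh: 0.73, act_max: 2.8, note: "HEK 293"}
    doses: {therapeutic: 0.5}
  amiodarone:
    channels:
      I_Na:   {mode: block, ic50: 40.4,  nh: 0.75, note: "rabbit"}
      I_NaL:  {mode: block, ic50: 9.0,   nh: 0.4,  note: "MANTA"}
      I_CaL:  {mode: block, ic50: 5.8,   nh: 1.0,  note: "guinea pig"}
      I_Kr:   {mode: block, ic50: 0.03,  nh: 1.0,  note: "HEK 293"}
      I_Ks:   {mode: block, ic50: 3.84,  nh: 0.63, note: "guinea pig"}
      I_NaK:  {mode: block, ic50: 15.6,  nh: 1.0,  note: "rabbit"}
      I_NaCa: {mode: block, ic50: 3.3,   nh: 1.0,  note: "guinea pig"}
    doses: {high: 0.005, medium: 0.0005, low: 0.00005}
  verapamil:
    channels:
      I_Na:   {mode: block, ic50: 7.221,  nh: 0.95, note: "HEK 293"}
      I_NaL:  {mode: block, ic50: 6.094,  nh: 1.24, note: "HEK 293"}
      I_CaL:  {mode: block, ic50: 0.0794, nh: 0.69, note: "CHO cell"}
      I_Kr:   {mode: block, ic50: 0.831,  nh: 1.17, note: "HEK 293"}
      I_K1:   {mode: block, ic50: 9.033,  nh: 1.0,  note: "HEK 293"}
      I_Ks:   {mode: block, ic50: 65.587, nh: 0.92, note: "HEK 293"}
    doses: {high: 0.3, medium: 0.03, low: 0.003}
  nifedipine:
    channels:
      I_Na:   {mode: block, ic50: 56.2,  nh: 0.59, note: "human"}
      I_CaL:  {mode: block, ic50: 0.3,   nh: 1.0,  note: "guinea pig"}
      I_to:   {mode: block, ic50: 26.8,  nh: 0.97, note: "human"}
      I_Kr:   {mode: block, ic50: 275.0, nh: 0.9,  note: "guinea pig"}
      I_K1:   {mode: block, ic50: 260.0, nh: 0.85, note: "guinea pig"}
      I_Ks:   {mode: block, ic50: 360.0, nh: 0.97, note: "guinea pig"}
    doses: {high: 0.05, medium: 0.005, low: 0.0005}
  quinidine:
    channels:
      I_Na:   {mode: block, ic50: 17.0,  nh: 0.92, note: "guinea pig"}
      I_NaL:  {mode: block, ic50: 12.0,  nh: 1.0,  note: "rabbit"}
      I_CaL:  {mode: block, ic50: 14.9,  nh: 1.1,  note: "guinea pig"}
      I_to:   {mode: block, ic50: 21.8,  nh: 0.67, note: "human"}
      I_Kr:   {mode: block, ic50: 0.41,  nh: 0.76, note: "HEK 293"}
      I_K1:   {mode: block, ic50: 42.6,  nh: 0.25, note: "human"}
      I_Ks:   {mode: block, ic50: 44.0,  nh: 1.8,  note: "CHO cell"}
    doses: {high: 10.0, medium: 1.0, low: 0.1}
  vanoxerine:
    channels:
      I_Na:   {mode: block, ic50: 0.0346, nh: 0.97, note: "HEK 293"}
      I_NaL:  {mode: block, ic50: 0.0852, nh: 1.62, note: "HEK 293"}
      I_CaL:  {mode: block, ic50: 0.0162, nh: 0.63, note: "CHO cell"}
      I_to:   {mode: block, ic50: 2.0,    nh: 1.0,  note: "mouse L cells"}
      I_Kr:   {mode: block, ic50: 0.0093, nh: 1.11, note: "HEK 293"}
      I_K1:   {mode: block, ic50: 98.142, nh: 1.0,  note: "HEK 293"}
      I_Ks:   {mode: block, ic50: 2.9,    nh: 1.0,  note: "CHO cell"}
    doses: {high: 0.05, medium: 0.005, low: 0.0005}
  bepridil:
    channels:
      I_Na:   {mode: block, ic50: 0.517,  nh: 1.14, note: "HEK 293"}
      I_NaL:  {mode: block, ic50: 0.411,  nh: 1.72, note: "HEK 293"}
      I_CaL:  {mode: block, ic50: 0.157,  nh: 1.08, note: "CHO cell"}
      I_Kr:   {mode: block, ic50: 0.0738, nh: 1.33, note: "HEK 293"}
      I_K1:   {mode: block, ic50: 66.536, nh: 1.0,  note: "HEK 293"}
      I_Ks:   {mode: block, ic50: 6.156,  nh: 2.33, note: "HEK 293"}
    doses: {high: 0.1, medium: 0.01, low: 0.001}
  kb130015:
    channels:
      I_Kr:   {mode: activate, ec50: 12.2, nh: 1.1, act_max: 4.7, note: "HEK 293"}
    doses: {therapeutic: 5.0}
  ica-105574:
    channels:
      I_Kr:   {mode: activate, ec50: 0.42, nh: 2.5, act_max: 5.5, note: "HEK 293"}
    doses: {therapeutic: 0.25}
  ns1643:
    channels:
      I_Kr:   {mode: activate, ec50: 10.4, nh: 1.8, act_max: 1.5, note: "Xenopus oocytes"}
    doses: {therapeutic: 30.0}
  ns3623:
    channels:
      I_Kr:   {mode: activate, ec50: 79.4, nh: 1.3, act_max: 2.9, note: "Xenopus oocytes"}
    doses: {therapeutic: 85.0}
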