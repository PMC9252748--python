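# Emulation of a melt with a scarcely resolved intermediate: N <=> I <=> D
# with overlapping transitions (apparent midpoint ~50 degC at 1 degC/min).
# The intermediate band sits close to, but slightly off, the line between the
# native and denatured bands, so conventional 2-D signals blend both
# transitions into one while a small third SVD component (~0.2% explained
# variance, autocorrelations > 0.8) resolves them.
scheme: three_state_rev
thermo:
  tm1: 47.5
  dh1: 350.0
  tm2: 52.5
  dh2: 420.0
state_spectra:
  N: {center: 330.0, width: 24.0, amplitude: 1.0}
  I: {center: 341.0, width: 18.0, amplitude: 0.85}
  D: {center: 352.0, width: 28.0, amplitude: 0.62}
wavelengths: {start: 300.0, stop: 450.0, step: 1.0}
temperatures: {start: 20.0, stop: 90.0, num: 71}
scan_rate: 1.0
noise_sd: 0.01
signal_baselines:
  N: [1.0, 0.0]
  I: [0.65, 0.0]
  D: [0.3, 0.0]
dsc_baselines:
  N: [0.0, 0.0]
  D: [3.0, 0.0]
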