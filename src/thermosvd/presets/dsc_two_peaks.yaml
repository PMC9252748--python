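# Three-state thermogram with two resolved excess-heat-capacity peaks,
# for exercising DSC fitting alongside spectral data.
scheme: three_state_rev
thermo:
  tm1: 45.0
  dh1: 300.0
  tm2: 55.0
  dh2: 400.0
state_spectra:
  N: {center: 330.0, width: 24.0, amplitude: 1.0}
  I: {center: 341.0, width: 26.0, amplitude: 0.80}
  D: {center: 352.0, width: 28.0, amplitude: 0.62}
wavelengths: {start: 300.0, stop: 450.0, step: 1.0}
temperatures: {start: 15.0, stop: 85.0, num: 281}
scan_rate: 1.0
noise_sd: 0.02
dsc_baselines:
  N: [10.0, 0.02]
  D: [13.0, 0.02]
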