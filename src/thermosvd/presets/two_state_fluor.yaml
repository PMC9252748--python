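# Clean two-state fluorescence melt: N <=> D, midpoint 50 degC,
# tryptophan-like red shift and quench on unfolding, 1 degC/min.
scheme: two_state_rev
thermo:
  tm1: 50.0
  dh1: 400.0
state_spectra:
  N: {center: 330.0, width: 24.0, amplitude: 1.0}
  D: {center: 352.0, width: 28.0, amplitude: 0.62}
wavelengths: {start: 300.0, stop: 450.0, step: 1.0}
temperatures: {start: 20.0, stop: 90.0, num: 150}
scan_rate: 1.0
noise_sd: 0.01
signal_baselines:
  N: [1.0, 0.0]
  D: [0.3, 0.0]
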