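# Kinetically controlled irreversible melt N -> D; the apparent midpoint
# shifts upward with the heating rate (simulate at several scan rates by
# overriding scan_rate).
scheme: two_state_irrev
thermo:
  ea: 300.0
  tf: 60.0
state_spectra:
  N: {center: 330.0, width: 24.0, amplitude: 1.0}
  D: {center: 352.0, width: 28.0, amplitude: 0.62}
wavelengths: {start: 300.0, stop: 450.0, step: 1.0}
temperatures: {start: 20.0, stop: 90.0, num: 141}
scan_rate: 1.0
noise_sd: 0.005
signal_baselines:
  N: [1.0, 0.0]
  D: [0.3, 0.0]
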