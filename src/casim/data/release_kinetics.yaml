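# Kinetic targets for the SR Ca2+ release-rate waveform, one column per
# fiber type: peak amplitude, 10-90% rise time, half-width and 90-10% decay
# time of the flux elicited by one action potential, the per-AP scale
# factors f_rel used in a 100 Hz train (first AP unscaled), and the
# single-AP released amount (time integral of the flux, sarcoplasm
# referenced) used as the optional fifth fitting target.
T2_ms: 10.0
fibers:
  I:
    peak_amplitude: 64.8     # uM ms^-1
    rise_10_90: 1.7          # ms
    half_width: 1.9          # ms
    decay_90_10: 2.4         # ms
    f_rel: [1.0, 0.17, 0.10, 0.10, 0.10]
    integral: 145.48         # uM
  IIA:
    peak_amplitude: 153.6
    rise_10_90: 1.2
    half_width: 1.4
    decay_90_10: 1.8
    f_rel: [1.0, 0.18, 0.11, 0.11, 0.10]
    integral: 254.58
  IIX:
    peak_amplitude: 238.8
    rise_10_90: 1.2
    half_width: 1.3
    decay_90_10: 1.5
    f_rel: [1.0, 0.18, 0.17, 0.16, 0.15]
    integral: 346.68
  IIB:
    peak_amplitude: 244.5
    rise_10_90: 1.2
    half_width: 1.3
    decay_90_10: 1.5
    f_rel: [1.0, 0.17, 0.15, 0.15, 0.14]
    integral: 363.71
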