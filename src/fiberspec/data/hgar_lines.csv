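# Mercury-argon pencil lamp emission lines used for wavelength registration.
# Standard physical constants; relative_intensity is a nominal lamp-dependent
# weighting used by the simulator, not a physical constant.
wavelength_nm,relative_intensity
404.656,0.55
435.833,1.00
546.074,0.90
576.960,0.35
579.066,0.40
696.543,0.45
763.511,0.60
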