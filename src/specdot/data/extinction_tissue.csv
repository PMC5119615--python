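wavelength_nm,HbO2,Hb,water
690,0.000636,0.004726,0.0005
730,0.000898,0.002538,0.0019
750,0.001193,0.003236,0.0026
850,0.002437,0.001592,0.0043
930,0.002796,0.001755,0.0270
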