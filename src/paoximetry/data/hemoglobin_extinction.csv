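wavelength_nm,eps_hbo,eps_hbd
750,518.0,1405.24
800,816.0,761.72
850,1058.0,691.32
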