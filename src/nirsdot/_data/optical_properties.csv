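# Baseline tissue optical properties per wavelength (literature-typical
# values for infant head tissue in the NIR window).
# mua: absorption coefficient, mm^-1; musp: reduced scattering, mm^-1.
tissue,wavelength_nm,mua,musp
ECT,780,0.017,0.74
ECT,850,0.019,0.64
CSF,780,0.004,0.30
CSF,850,0.004,0.30
GM,780,0.018,0.74
GM,850,0.019,0.67
WM,780,0.017,0.91
WM,850,0.021,0.85
homogeneous,780,0.017,0.80
homogeneous,850,0.019,0.70
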