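# Specific extinction coefficients of haemoglobin, cm^-1 / (mol/L).
# Compiled tabulated absorption spectra of human oxy- and
# deoxy-haemoglobin (Prahl compilation of the Gratzer/Kollias data).
wavelength_nm,hbo,hbr
780,710.0,1075.6
850,1058.0,691.6
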