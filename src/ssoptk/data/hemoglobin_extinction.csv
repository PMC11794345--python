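# Molar extinction coefficients of human hemoglobin, cm^-1 / (mol/L).
# Interpolated and rounded from the standard tabulated compilation
# (S. Prahl, Optical absorption of hemoglobin, OMLC).
# source_version: omlc-1999-interp-v1
wavelength_nm,eps_hbo2,eps_hb
665,310.0,3141.0
860,1070.0,740.0
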