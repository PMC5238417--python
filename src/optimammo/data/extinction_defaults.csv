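# Specific absorption (extinction) coefficients of the five breast-tissue
# constituents at the instrument wavelengths.  Literature-like default
# values compiled from published chromophore spectra (hemoglobin molar
# extinctions; pure water, lipid and collagen type I absorption divided by
# the pure-constituent density); synthetic convenience table, not a
# measured dataset.
# Units: Hb, HbO2 in cm^-1 per uM; water, lipid, collagen in cm^-1 per (mg/cm^3).
wavelength_nm,Hb,HbO2,water,lipid,collagen
635,9.67e-3,7.83e-4,3.0e-6,3.6e-6,2.50e-4
685,4.95e-3,6.26e-4,5.0e-6,4.9e-6,1.79e-4
785,2.42e-3,1.69e-3,2.3e-5,7.1e-6,1.29e-4
905,1.71e-3,2.76e-3,7.4e-5,3.3e-5,2.14e-4
930,1.66e-3,2.95e-3,1.25e-4,1.20e-4,2.00e-4
975,1.58e-3,3.11e-3,4.60e-4,4.9e-5,1.86e-4
1060,1.27e-3,2.42e-3,1.40e-4,5.2e-5,3.21e-4
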