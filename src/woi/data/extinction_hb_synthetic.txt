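# Synthetic hemoglobin extinction spectra (stand-in for the standard compiled
# tables): molar extinction coefficients in cm^-1 M^-1 on a 10 nm grid.
# Values reproduce the qualitative features of oxy-/deoxyhemoglobin absorption
# (beta/alpha HbO2 bands near 542/577 nm, isosbestic points near 530/570 nm,
# deoxy > oxy in the red) and are intended for testing, not quantitation.
# wavelength_nm  eps_HbO2  eps_Hb
  450    62816   103292
  460    44480    91592
  470    33209    67332
  480    26629    50240
  490    23684    37020
  500    20932    26630
  510    20035    25774
  520    24202    28324
  530    39036    39037
  540    53236    46592
  550    43016    52276
  560    32613    53412
  570    45072    45072
  580    50104    37020
  590    14677    26600
  600     3200    14677
  610     1506     9444
  620      942     7553
  630      610     5149
  640      442     4345
  650      368     3750
  660      319     3227
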