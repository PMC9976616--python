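# Synthetic LED emission spectrum, Gaussian centered at 470 nm (sd 11 nm), unit area.
# wavelength_nm  relative_intensity
  440 8.839950e-04
  442 1.427658e-03
  444 2.230701e-03
  446 3.372112e-03
  448 4.931802e-03
  450 6.978346e-03
  452 9.553059e-03
  454 1.265248e-02
  456 1.621257e-02
  458 2.009886e-02
  460 2.410649e-02
  462 2.797305e-02
  464 3.140428e-02
  466 3.410994e-02
  468 3.584398e-02
  470 3.644136e-02
  472 3.584398e-02
  474 3.410994e-02
  476 3.140428e-02
  478 2.797305e-02
  480 2.410649e-02
  482 2.009886e-02
  484 1.621257e-02
  486 1.265248e-02
  488 9.553059e-03
  490 6.978346e-03
  492 4.931802e-03
  494 3.372112e-03
  496 2.230701e-03
  498 1.427658e-03
  500 8.839950e-04
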