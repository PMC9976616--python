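# Synthetic LED emission spectrum, Gaussian centered at 625 nm (sd 9 nm), unit area.
# wavelength_nm  relative_intensity
  595 1.714599e-04
  597 3.508641e-04
  599 6.833899e-04
  601 1.266927e-03
  603 2.235568e-03
  605 3.754721e-03
  607 6.002342e-03
  609 9.133079e-03
  611 1.322717e-02
  613 1.823351e-02
  615 2.392361e-02
  617 2.987697e-02
  619 3.551402e-02
  621 4.018060e-02
  623 4.326995e-02
  625 4.435164e-02
  627 4.326995e-02
  629 4.018060e-02
  631 3.551402e-02
  633 2.987697e-02
  635 2.392361e-02
  637 1.823351e-02
  639 1.322717e-02
  641 9.133079e-03
  643 6.002342e-03
  645 3.754721e-03
  647 2.235568e-03
  649 1.266927e-03
  651 6.833899e-04
  653 3.508641e-04
  655 1.714599e-04
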