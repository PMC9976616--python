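# Synthetic LED emission spectrum, Gaussian centered at 590 nm (sd 8 nm), unit area.
# wavelength_nm  relative_intensity
  560 4.407897e-05
  562 1.090965e-04
  564 2.536570e-04
  566 5.540377e-04
  568 1.136812e-03
  570 2.191262e-03
  572 3.967862e-03
  574 6.749561e-03
  576 1.078577e-02
  578 1.619136e-02
  580 2.283347e-02
  582 3.024944e-02
  584 3.764603e-02
  586 4.401267e-02
  588 4.833846e-02
  590 4.987289e-02
  592 4.833846e-02
  594 4.401267e-02
  596 3.764603e-02
  598 3.024944e-02
  600 2.283347e-02
  602 1.619136e-02
  604 1.078577e-02
  606 6.749561e-03
  608 3.967862e-03
  610 2.191262e-03
  612 1.136812e-03
  614 5.540377e-04
  616 2.536570e-04
  618 1.090965e-04
  620 4.407897e-05
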