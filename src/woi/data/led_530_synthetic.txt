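# Synthetic LED emission spectrum, Gaussian centered at 530 nm (sd 16 nm), unit area.
# wavelength_nm  relative_intensity
  500 4.537498e-03
  502 5.691298e-03
  504 7.027815e-03
  506 8.543650e-03
  508 1.022541e-02
  510 1.204848e-02
  512 1.397648e-02
  514 1.596164e-02
  516 1.794615e-02
  518 1.986458e-02
  520 2.164719e-02
  522 2.322405e-02
  524 2.452948e-02
  526 2.550663e-02
  528 2.611150e-02
  530 2.631629e-02
  532 2.611150e-02
  534 2.550663e-02
  536 2.452948e-02
  538 2.322405e-02
  540 2.164719e-02
  542 1.986458e-02
  544 1.794615e-02
  546 1.596164e-02
  548 1.397648e-02
  550 1.204848e-02
  552 1.022541e-02
  554 8.543650e-03
  556 7.027815e-03
  558 5.691298e-03
  560 4.537498e-03
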