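# Canonical mirror-pair seed template in atlas millimetres.
# ap_mm: posterior offset from the anterior midline suture along the midline;
# lat_mm: absolute lateral offset; each row expands to a left and right seed.
# name           ap_mm  lat_mm
frontal           0.8    1.0
motor             1.7    1.5
somatosensory     3.3    2.8
retrosplenial     5.2    0.8
auditory          4.6    4.0
visual            6.3    2.2
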