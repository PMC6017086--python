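# 1
# 0.0 0.1 20 0
  0.05 4.8213
  0.15 3.1207
  0.25 1.9016
  0.35 0.9441
  0.45 0.3312
  0.55 0.0418
  0.65 0.0000
  0.75 0.2841
  0.85 0.8372
  0.95 1.6570
  1.05 2.7011
  1.15 3.9984
  1.25 5.5210
  1.35 7.2995
  1.45 9.3112
  1.55 11.5671
  1.65 14.0803
  1.75 16.8312
  1.85 19.8289
  1.95 23.0714
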