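# Package reference stain used as the normalization target.
# Row 1 = hematoxylin, row 2 = eosin, as unit optical-density direction
# vectors over (R, G, B). The hematoxylin vector has the larger blue
# component, which is also how estimated vectors are labelled.
stain_matrix:
  - [0.6512, 0.7012, 0.2905]
  - [0.0701, 0.9915, 0.1102]
max_concentrations: [1.9705, 1.0308]
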