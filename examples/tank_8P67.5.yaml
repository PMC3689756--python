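label: 8P67.5
tank:
  radius_cm: 75.0
  water_depth_cm: 10.0
  boundary_contrast: 17.0
channels:
- pos:
  - 75.0
  - 0.0
  neg:
  - 28.701257427381737
  - 69.2909649383465
- pos:
  - -53.03300858899106
  - 53.033008588991066
  neg:
  - -69.29096493834652
  - -28.701257427381726
- pos:
  - -1.3777276490407723e-14
  - -75.0
  neg:
  - 69.29096493834652
  - -28.701257427381716
- pos:
  - 53.033008588991066
  - 53.03300858899106
  neg:
  - -28.70125742738173
  - 69.2909649383465
- pos:
  - -75.0
  - 9.184850993605149e-15
  neg:
  - -28.701257427381712
  - -69.29096493834652
- pos:
  - 53.03300858899105
  - -53.03300858899107
  neg:
  - 69.2909649383465
  - 28.701257427381734
- pos:
  - 4.592425496802574e-15
  - 75.0
  neg:
  - -69.2909649383465
  - 28.70125742738174
- pos:
  - -53.03300858899107
  - -53.03300858899106
  neg:
  - 28.70125742738175
  - -69.29096493834649
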