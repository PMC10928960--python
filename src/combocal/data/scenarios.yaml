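# Combination-toxicity scenarios used in the comparison study.
# Rows index drug A levels, columns drug B levels; target DLT probability 0.30.
target: 0.30
scenarios:
  S1:
    - [0.05, 0.10, 0.15]
    - [0.10, 0.15, 0.20]
    - [0.15, 0.20, 0.30]
  S2:
    - [0.05, 0.10, 0.15]
    - [0.10, 0.20, 0.30]
    - [0.20, 0.30, 0.45]
  S3:
    - [0.02, 0.05, 0.10]
    - [0.10, 0.15, 0.20]
    - [0.20, 0.30, 0.45]
  S4:
    - [0.05, 0.10, 0.15]
    - [0.10, 0.20, 0.30]
    - [0.20, 0.45, 0.60]
  S5:
    - [0.02, 0.05, 0.15]
    - [0.20, 0.30, 0.45]
    - [0.45, 0.55, 0.65]
  S6:
    - [0.10, 0.15, 0.30]
    - [0.15, 0.30, 0.45]
    - [0.30, 0.45, 0.60]
  S7:
    - [0.10, 0.20, 0.45]
    - [0.15, 0.30, 0.50]
    - [0.30, 0.50, 0.60]
  S8:
    - [0.05, 0.10, 0.20]
    - [0.10, 0.20, 0.30]
    - [0.30, 0.45, 0.55]
  S9:
    - [0.10, 0.15, 0.30]
    - [0.30, 0.40, 0.50]
    - [0.40, 0.50, 0.60]
  S10:
    - [0.15, 0.30, 0.45]
    - [0.30, 0.45, 0.55]
    - [0.45, 0.55, 0.65]
  S11:
    - [0.02, 0.05, 0.10]
    - [0.30, 0.45, 0.60]
    - [0.45, 0.60, 0.75]
  S12:
    - [0.20, 0.30, 0.45]
    - [0.45, 0.50, 0.55]
    - [0.65, 0.70, 0.75]
  S13:
    - [0.30, 0.45, 0.50]
    - [0.45, 0.50, 0.55]
    - [0.50, 0.55, 0.60]
  S14:
    - [0.45, 0.50, 0.55]
    - [0.50, 0.55, 0.60]
    - [0.55, 0.60, 0.65]
  S15:
    - [0.10, 0.10, 0.10]
    - [0.10, 0.10, 0.10]
    - [0.10, 0.10, 0.10]
  S16:
    - [0.10, 0.30, 0.45]
    - [0.30, 0.45, 0.60]
  S17:
    - [0.10, 0.15, 0.30]
    - [0.30, 0.45, 0.60]
  S18:
    - [0.10, 0.20, 0.30]
    - [0.15, 0.30, 0.50]
  S19:
    - [0.10, 0.15, 0.20, 0.30]
    - [0.30, 0.40, 0.50, 0.60]
  S20:
    - [0.10, 0.20, 0.30, 0.40]
    - [0.20, 0.30, 0.40, 0.50]
  S21:
    - [0.15, 0.20, 0.25, 0.30]
    - [0.40, 0.45, 0.50, 0.55]
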