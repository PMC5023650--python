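name: recalibrated
variables:
  age:
  - points: 1
    upper: 47.0
    upper_closed: false
  - points: 2
    lower: 47.0
    lower_closed: true
    upper: 59.0
    upper_closed: true
  - points: 3
    lower: 59.0
    lower_closed: false
  pf_ratio:
  - points: 1
    lower: 158.0
    lower_closed: false
  - points: 2
    lower: 105.0
    lower_closed: true
    upper: 158.0
    upper_closed: true
  - points: 3
    upper: 105.0
    upper_closed: false
  pmax:
  - points: 1
    upper: 30.0
    upper_closed: false
  - points: 2
    lower: 30.0
    lower_closed: true
    upper: 33.0
    upper_closed: true
  - points: 3
    lower: 33.0
    lower_closed: false
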