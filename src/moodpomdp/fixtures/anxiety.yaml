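format: moodpomdp-model/1
name: anxiety
states:
- stressful
- not_stressful
observations:
- stress_signal
- pleasure_signal
actions:
- attenuate_pleasure
- amplify_pleasure
- attenuate_stress
- amplify_stress
- wait
transition:
- - - 0.83
    - 0.17000000000000004
  - - 0.28
    - 0.72
- - - 0.83
    - 0.17000000000000004
  - - 0.28
    - 0.72
- - - 0.83
    - 0.17000000000000004
  - - 0.28
    - 0.72
- - - 0.83
    - 0.17000000000000004
  - - 0.28
    - 0.72
- - - 0.83
    - 0.17000000000000004
  - - 0.28
    - 0.72
likelihood:
- - - 0.60475
    - 0.39525
  - - 0.57925
    - 0.42074999999999996
- - - 0.3651877133105802
    - 0.6348122866894198
  - - 0.3377926421404682
    - 0.6622073578595318
- - - 0.45475
    - 0.54525
  - - 0.42924999999999996
    - 0.5707500000000001
- - - 0.6970684039087948
    - 0.30293159609120524
  - - 0.6710963455149501
    - 0.3289036544850499
- - - 0.535
    - 0.46499999999999997
  - - 0.505
    - 0.495
reward:
- - -1.3700170245560075
  - -1.3746778071564225
- - -1.3412591120053585
  - -1.3314250000807406
- - -1.3793995113721915
  - -1.3755691982772225
- - -1.317794373903698
  - -1.3282623408280676
- - -1.385646896538645
  - -1.3863079106800782
discount: 0.95
metadata:
  version: 1
  preference_pleasure: 0.51
  builder:
    stress_signal_given_stressful: 0.535
    stress_signal_given_not_stressful: 0.505
    stay_stressful: 0.83
    stay_not_stressful: 0.72
    amplify_gain: 2.0
    attenuate_factor: 0.85
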