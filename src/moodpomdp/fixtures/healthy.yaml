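format: moodpomdp-model/1
name: healthy
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
- - - 0.88
    - 0.12
  - - 0.12
    - 0.88
- - - 0.88
    - 0.12
  - - 0.12
    - 0.88
- - - 0.88
    - 0.12
  - - 0.12
    - 0.88
- - - 0.88
    - 0.12
  - - 0.12
    - 0.88
- - - 0.88
    - 0.12
  - - 0.12
    - 0.88
likelihood:
- - - 0.96
    - 0.040000000000000036
  - - 0.84
    - 0.16000000000000003
- - - 0.2857142857142857
    - 0.7142857142857143
  - - 0.024390243902439046
    - 0.975609756097561
- - - 0.16000000000000003
    - 0.84
  - - 0.04000000000000001
    - 0.96
- - - 0.975609756097561
    - 0.024390243902439046
  - - 0.7142857142857143
    - 0.2857142857142857
- - - 0.8
    - 0.19999999999999996
  - - 0.2
    - 0.8
reward:
- - -0.9117248332087129
  - -1.1145879027589929
- - -1.2237571979988204
  - -0.8482726147894156
- - -1.0862321215848028
  - -0.8760720790009843
- - -0.8838174242893923
  - -1.2434113867811605
- - -1.2028708604007265
  - -1.1846284278168797
discount: 0.95
metadata:
  version: 1
  preference_pleasure: 0.51
  builder:
    stress_signal_given_stressful: 0.8
    stress_signal_given_not_stressful: 0.2
    stay_stressful: 0.88
    stay_not_stressful: 0.88
    amplify_gain: 10.0
    attenuate_factor: 0.2
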