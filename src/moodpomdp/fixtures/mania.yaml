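format: moodpomdp-model/1
name: mania
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
- - - 0.6
    - 0.4
  - - 0.050000000000000044
    - 0.95
- - - 0.6
    - 0.4
  - - 0.050000000000000044
    - 0.95
- - - 0.6
    - 0.4
  - - 0.050000000000000044
    - 0.95
- - - 0.6
    - 0.4
  - - 0.050000000000000044
    - 0.95
- - - 0.6
    - 0.4
  - - 0.050000000000000044
    - 0.95
likelihood:
- - - 0.352
    - 0.648
  - - 0.244
    - 0.756
- - - 0.2447552447552448
    - 0.7552447552447552
  - - 0.136986301369863
    - 0.863013698630137
- - - 0.15400000000000003
    - 0.846
  - - 0.08800000000000008
    - 0.9119999999999999
- - - 0.368421052631579
    - 0.631578947368421
  - - 0.22222222222222232
    - 0.7777777777777777
- - - 0.28
    - 0.72
  - - 0.16000000000000003
    - 0.84
reward:
- - -1.312460581557502
  - -1.2636709581595003
- - -1.1989645216545015
  - -1.1149611745004073
- - -1.0851507145150068
  - -1.0141683307686644
- - -1.3076990457894007
  - -1.2402937653442598
- - -1.2357085924761084
  - -1.1540430536352404
discount: 0.95
metadata:
  version: 1
  preference_pleasure: 0.51
  mirror_of: depression
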