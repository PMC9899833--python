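# Shipped study-design library for the synthetic-data generator.
# arms: [dose mg, n subjects, QD days, single-dose run-in flag]
# times are hours post-dose (run-in / first QD dose / last-day dose);
# trough_days are QD day numbers sampled pre-dose.
FCN-159-001:
  cancer_type: melanoma
  arms:
    - [0.2, 3, 21, true]
    - [0.5, 3, 21, true]
    - [1.0, 3, 21, true]
    - [2.0, 4, 21, true]
    - [4.0, 4, 21, true]
    - [6.0, 4, 28, true]
    - [8.0, 4, 28, true]
    - [12.0, 4, 28, true]
    - [15.0, 4, 28, true]
  run_in_times: [0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24, 36, 48, 72]
  day1_times: []
  trough_days: []
  last_day_times: [0, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24]
FCN-159-002:
  cancer_type: nf1
  arms:
    - [4.0, 3, 28, false]
    - [6.0, 3, 28, false]
    - [8.0, 3, 28, false]
    - [12.0, 3, 28, false]
  run_in_times: []
  day1_times: [0.5, 1, 2, 3, 4, 6, 8, 12]
  trough_days: [8, 15, 22]
  last_day_times: [0, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24]
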