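# Cohort simulation config for test battery 32; defaults apply to any
# field omitted here.  Run:
#   ncptkit run-all --config examples/cohort_battery32.yaml --out-dir out/
seed: 17
simulate:
  n: 3000
  battery_id: 32
  pause_rate: 0.02        # >24 h pause between subtests
  interleave_rate: 0.01   # second test started inside the first
  slow_trails_rate: 0.01  # trail making over 15 minutes (ignored if no trails)
  dropout_rate: 0.03      # battery abandoned part-way
reference:
  kind: census            # or: uniform | match_cohort | explicit
normalize:
  target_mean: 100
  target_sd: 15
  tie_policy: midrank     # or: ordinal
norms:
  gender_set: [m, f]
  min_bin_n: 20
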