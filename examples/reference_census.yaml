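# Census-like reference composition over the 18 age x education bins
# (flat index k = 3*age_bin + edu_bin; age bins [18-29]..[70-99], education
# bins high_school / college / post_college).  Proportions must sum to 1.
kind: explicit
strict: true
proportions:
  - 0.06001000
  - 0.08823000
  - 0.02176000
  - 0.05577400
  - 0.08200200
  - 0.02022400
  - 0.05612700
  - 0.08252100
  - 0.02035200
  - 0.05612700
  - 0.08252100
  - 0.02035200
  - 0.05471500
  - 0.08044500
  - 0.01984000
  - 0.07024700
  - 0.10328100
  - 0.02547200
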