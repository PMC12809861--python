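# Fixed disease-liability parameter profiles.
# "maudsley_*" is the main analysis set; "polderman_*" the sensitivity set.
# polderman_sz e2 is completed to 0.22 so the variance proportions sum to 1.
maudsley_sz:
  h2: 0.84
  c2: 0.00
  e2: 0.16
  prevalence: 0.0075
maudsley_bd1:
  h2: 0.85
  c2: 0.00
  e2: 0.15
  prevalence: 0.0032
maudsley_broad:
  h2: 0.90
  c2: 0.00
  e2: 0.10
  prevalence: 0.017
polderman_sz:
  h2: 0.77
  c2: 0.01
  e2: 0.22
  prevalence: 0.01
polderman_bd1:
  h2: 0.76
  c2: 0.00
  e2: 0.24
  prevalence: 0.01
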