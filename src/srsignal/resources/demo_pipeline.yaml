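# Demo end-to-end run on a synthetic dataset with the bundled dictionaries.
seed: 1
simulate:
  paperlike: true
  n_reports: 20000
year_window: [2016, 2020]
signal:
  chi2_variant: yates
  ic_variant: n4
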