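{
  "authority.tsv": "50428450cc2843dc0214b99a582373c4308b1b0361b1b0d06bf528f0a2d0f22d",
  "records_finfish.tsv": "26dee379262cf8af84e867311edc0c86f0968c2dddd04b185eb767dbd34ce287",
  "records_invertebrates.tsv": "8d6d8e0dc77826360987ecdfa7da1ec4bb6ece00e1fee106a1c44a7d6d272ff9",
  "status.tsv": "54048179a839be9d5b4f965eb62453159484bd4d4c339717027ea79b1fc09e96",
  "table_counts.tsv": "85b1f2b1e895bf6fcecb5d891c961056ceff1c33c7c7ba26607926c8a2eeff9d",
  "year_counts.tsv": "0b66d17e1f21f06db730875a118907eeb3810455cbae2b5bcc936a8c52bb1c87"
}
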