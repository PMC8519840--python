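# The seven-ratio diet panel: molar AA:C ratios at fixed sucrose molarity.
sucrose_molarity: 0.5
ratios:
  - "0:1"
  - "1:250"
  - "1:100"
  - "1:75"
  - "1:50"
  - "1:25"
  - "1:10"
# Optional: path (relative to this file) to a two-column amino-acid mix table.
# Omit to use the built-in equimolar ten-amino-acid mix.
mix_file: pollen_mix_synthetic.tsv
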