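# Signals-only protocol: each protein predicted from the others
# (2/3-1/3 split x 100 repeats, leave-one-out CV inside the training part).
table: data/supplementary/s5_dream8_bt20.csv
schema: examples/dream8_schema.yaml
kind: powerlaw
repeats: 100
seed: 0
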