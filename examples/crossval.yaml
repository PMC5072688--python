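# Repeated 5-fold cross-validation of the power-law fate model within one
# cell line (5 folds x 200 repeats = 1000 evaluations).
table: data/supplementary/lee_bt20.csv
schema: examples/lee_schema.yaml
fate: apoptosis
kind: powerlaw
folds: 5
repeats: 200
epsilon: 1.0e-6
thresholds: [0.7, 0.8, 0.9]
seed: 0
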