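# Virtual protein knock-down ranked against drugged observations.
control_table: data/control.csv
drugged_table: data/drugged.csv
schema: examples/lee_schema.yaml
fate: apoptosis
mode: blocked        # blocked: ascending RMSE; enhanced: descending
rule: replace        # or "additive" to keep direct fate coefficients
epsilon: 1.0e-6
seed: 0
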