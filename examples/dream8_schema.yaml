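# Signals-only schema for the per-protein prediction protocol: all columns
# are signals, there is no fate column.
protein_1: signal
protein_2: signal
protein_3: signal
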