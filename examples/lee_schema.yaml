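# Column-role map for a breast-cancer observation table: every column must
# be assigned exactly one role (metadata | signal | fate).  Replace the
# protein names with the columns of your converted table.
treatment: metadata
time_point: metadata
replicate: metadata
EGFR: signal
AKT: signal
ERK: signal
STAT3: signal
apoptosis: fate
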