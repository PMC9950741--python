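term	impact
transcript_ablation	HIGH
splice_acceptor_variant	HIGH
splice_donor_variant	HIGH
stop_gained	HIGH
frameshift_variant	HIGH
stop_lost	HIGH
start_lost	HIGH
missense_variant	MODERATE
inframe_insertion	MODERATE
inframe_deletion	MODERATE
protein_altering_variant	MODERATE
synonymous_variant	LOW
splice_region_variant	LOW
stop_retained_variant	LOW
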