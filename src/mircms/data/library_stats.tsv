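key	value
total_tags_millions	46.0
shared_tags_millions	33.8
cms_specific_tags_millions	5.7
control_specific_tags_millions	6.4
unique_tags_millions	12.2
n_known_mirnas	289
n_known_families	69
n_novel_mirnas	426
n_novel_down	49
n_novel_up	27
n_known_down	10
n_known_up	1
n_targets	376
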