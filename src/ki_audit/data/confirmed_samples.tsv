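sample_id	generation	parent_f0	is_ki
268-1	F1	268	true
283-1	F1	283	true
306-1	F1	306	true
316-2	F1	316	true
B6J	control	.	false
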