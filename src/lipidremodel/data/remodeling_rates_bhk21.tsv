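# Primary remodeling rate constants (h^-1) inferred from six BHK21 pulse-chase
# experiments with distinct deuterated diacyl-PE precursors; one row group per
# (experiment, position, initial chain). Entries absent here are structurally
# missing (unobserved species or negligible flux), not zero.
position	experiment	initial_chain	new_chain	rate
sn1	14:0-14:0	14:0	18:1	0.0889
sn1	14:0-14:0	14:0	18:0	0.0166
sn1	14:0-14:0	14:0	16:1	0.0261
sn1	14:1-14:1	14:1	18:1	0.5903
sn1	14:1-14:1	14:1	18:0	0.1083
sn1	18:3-18:3	18:3	18:1	0.2500
sn1	18:3-18:3	18:3	18:0	0.0650
sn1	18:3-18:3	18:3	16:1	0.0589
sn1	18:0-22:6	18:0	18:1	0.0673
sn1	18:0-18:1	18:0	18:1	0.0700
sn1	18:1-18:1	18:1	18:0	0.0019
sn1	18:1-18:1	18:1	16:1	0.0072
sn1	18:1-18:1	18:1	16:0	0.0041
sn2	14:0-14:0	14:0	18:1	0.5176
sn2	14:0-14:0	14:0	18:2	0.1520
sn2	14:1-14:1	14:1	18:1	0.1400
sn2	14:1-14:1	14:1	18:2	0.0998
sn2	14:1-14:1	14:1	16:1	0.1153
sn2	14:1-14:1	14:1	20:4	0.0769
sn2	18:3-18:3	18:3	18:1	0.0555
sn2	18:0-22:6	22:6	18:1	0.0724
sn2	18:0-22:6	22:6	20:4	0.1146
sn2	18:1-18:1	18:1	18:2	0.0029
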