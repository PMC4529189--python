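template	t1	t2	t3	t4	t5	t6	t7
linear_up	0	0.67	1.33	2	2.67	3.33	4
linear_down	4	3.33	2.67	2	1.33	0.67	0
early_peak	0	4	1.5	0.5	0	0	0
mid_peak	0	0	1.5	4	1.5	0	0
late_peak	0	0	0	0.3	1	4	0.8
early_dip	4	0	2.5	3.5	4	4	4
valley	4	2	0.5	0	0.5	2	4
saturating_rise	0	2.4	3.4	3.8	4	4	4
exponential_decay	4	1.2	0.4	0.1	0	0	0
delayed_rise	0	0	0	0	0.5	2	4
delayed_fall	4	4	4	4	3.5	2	0
zigzag_up	0	4	0	4	0	4	0
zigzag_down	4	0	4	0	4	0	4
square_pulse	0	3.8	4	4	4	3.8	0
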