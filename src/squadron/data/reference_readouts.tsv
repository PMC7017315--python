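# Reference steady-state readouts for the six HROC87 treatment scenarios.
node	untr.	+gef	+vem	+combi	+MEK-Inh	+BCL2-Inh
apoptosis	0.21	0.35	0.35	0.35	0.99	0.99
proliferation	0.5	0.5	0.5	0.2	0.0	0.5
(HGFR)*	0.97	0.6	0.97	0.4	0.97	0.97
ERK	0.71	0.59	0.59	0.3	0.0	0.71
(EGFR)*	0.5	0.3	0.4	0.3	0.5	0.5
AKT	0.2	0.16	0.2	0.24	0.2	0.2
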