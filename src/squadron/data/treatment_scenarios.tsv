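# Pre-stimulation clamps for the six HROC87 treatment scenarios.
# Rows: network nodes; columns: scenarios; blank cell = node left free.
node	untr.	+gef	+vem	+combi	+MEK-Inh	+BCL2-Inh
BRAF(V600)-Act	0.7	0.7	0.7	0.7	0.7	0.7
EGFR	0.5	0.5	0.5	0.5	0.5	0.5
HGFR	0.7	0.7	0.7	0.7	0.7	0.7
ERK-Inh	0.26	0.3	0.3	0.41	0.26	0.26
p53-Mut	0.2	0.2	0.2	0.2	0.2	0.2
Bcl2	0.31	0.3467	0.305	0.2252		
c-Myc-Inh	0.17	0.097	0.097		0.17	0.17
AKT	0.2	0.16	0.2	0.24	0.2	0.2
(EGFR)*		0.3	0.4	0.3		
(HGFR)*		0.6		0.4		
c-Myc-Act				0.09		
Gefitinib		1.0		1.0		
Vemurafenib			1.0	1.0		
MEK-Inhibitor					1.0	
Bcl2-Inhibitor						1.0
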