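contrast	gene_name	regulated_type	p_value	position	amino_acid	kegg_pathway	fisher_p
H/C	CACNA1D	Down	3.119E-05	802	S	Dopaminergic synapse	0.000058
S/H	CACNA1D	Up	1.507E-06	869	S	Dopaminergic synapse	0.000069
E/H	CACNA1D	Up	0.001828	1719	S	Dopaminergic synapse	0.000005
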