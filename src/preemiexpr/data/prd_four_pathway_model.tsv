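source	pathway	pathway_log_or	gene	gene_or
Reactome	Recycling Of Bile Acids And Salts	-1.49	SLC10A1	0.61
Reactome	Recycling Of Bile Acids And Salts	-1.49	SLC27A5	0.66
Reactome	Recycling Of Bile Acids And Salts	-1.49	SLCO1A2	0.71
Reactome	Transport Of Organic Anions	1.71	SLCO1A2	0.71
Reactome	Transport Of Organic Anions	1.71	SLCO3A1	1.27
Reactome	Transport Of Organic Anions	1.71	SLCO4A1	1.58
Reactome	Transport Of Organic Anions	1.71	SLCO4C1	1.45
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	ARHGEF18	0.93
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	CGN	0.84
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	F11R	0.77
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	FKBP1A	0.72
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	PARD3	0.58
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	PARD6A	0.88
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	PRKCZ	0.69
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	RHOA	0.76
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	RPS27A	0.85
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	SMURF1	0.91
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	TGFB1	1.07
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	TGFBR1	0.81
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	TGFBR2	1.09
Reactome	TGF-Beta Receptor Signaling In Epithelial To Mesenchyme Transition	-0.49	UBA52	0.87
Biocarta	Cell2Cell Pathway	-0.46	ACTN1	0.5
Biocarta	Cell2Cell Pathway	-0.46	CSK	0.86
Biocarta	Cell2Cell Pathway	-0.46	CTNNA1	0.87
Biocarta	Cell2Cell Pathway	-0.46	CTNNB1	1.01
Biocarta	Cell2Cell Pathway	-0.46	PECAM1	0.65
Biocarta	Cell2Cell Pathway	-0.46	PTK2	0.76
Biocarta	Cell2Cell Pathway	-0.46	PXN	0.76
Biocarta	Cell2Cell Pathway	-0.46	VCL	0.82
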