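# effective-FiO2 low-flow nasal cannula conversion grid, version 1
# cell = fraction of inspired gas supplied by the cannula for (weight_g row, flow_lpm column)
# model: min(1, flow / (0.3 L/min/kg * weight)); effective FiO2 = 0.21 + (set FiO2 - 0.21) * fraction
weight_g	0.00	0.25	0.50	0.75	1.00	1.25	1.50	1.75	2.00
500	0.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
750	0.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
1000	0.0000	0.8333	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
1250	0.0000	0.6667	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
1500	0.0000	0.5556	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
1750	0.0000	0.4762	0.9524	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
2000	0.0000	0.4167	0.8333	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
2250	0.0000	0.3704	0.7407	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
2500	0.0000	0.3333	0.6667	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000
2750	0.0000	0.3030	0.6061	0.9091	1.0000	1.0000	1.0000	1.0000	1.0000
3000	0.0000	0.2778	0.5556	0.8333	1.0000	1.0000	1.0000	1.0000	1.0000
3250	0.0000	0.2564	0.5128	0.7692	1.0000	1.0000	1.0000	1.0000	1.0000
3500	0.0000	0.2381	0.4762	0.7143	0.9524	1.0000	1.0000	1.0000	1.0000
3750	0.0000	0.2222	0.4444	0.6667	0.8889	1.0000	1.0000	1.0000	1.0000
4000	0.0000	0.2083	0.4167	0.6250	0.8333	1.0000	1.0000	1.0000	1.0000
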