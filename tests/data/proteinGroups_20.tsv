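Majority protein IDs	Gene names	Unique peptides	Reverse	Potential contaminant	Only identified by site	Intensity mock_r1	Intensity mock_r2	Intensity mock_r3	Intensity mock_r4	Intensity treat_r1	Intensity treat_r2	Intensity treat_r3	Intensity treat_r4	LFQ intensity mock_r1	LFQ intensity mock_r2	LFQ intensity mock_r3	LFQ intensity mock_r4	LFQ intensity treat_r1	LFQ intensity treat_r2	LFQ intensity treat_r3	LFQ intensity treat_r4
AT2G29970_SMXL7	SMXL7	5				1e+06	1.1e+06	1.2e+06	1.3e+06	900000	1e+06	1.1e+06	1.2e+06	1e+06	1.1e+06	1.2e+06	1.3e+06	900000	1e+06	1.1e+06	1.2e+06
REV__P02	P02	6	+			1.05e+06	1.155e+06	1.26e+06	1.365e+06	945000	1.05e+06	1.155e+06	1.26e+06	1.05e+06	1.155e+06	1.26e+06	1.365e+06	945000	1.05e+06	1.155e+06	1.26e+06
REV__P03	P03	7	+			1.1e+06	1.21e+06	0	0	990000	1.1e+06	1.21e+06	0	1.1e+06	1.21e+06	0	0	990000	1.1e+06	1.21e+06	0
CON__P04	P04	8		+		1.15e+06	1.265e+06	1.38e+06	1.495e+06	1.035e+06	1.15e+06	1.265e+06	1.38e+06	1.15e+06	1.265e+06	1.38e+06	1.495e+06	1.035e+06	1.15e+06	1.265e+06	1.38e+06
CON__P05	P05	9		+		1.2e+06	1.32e+06	1.44e+06	1.56e+06	1.08e+06	1.2e+06	1.32e+06	1.44e+06	1.2e+06	1.32e+06	1.44e+06	1.56e+06	1.08e+06	1.2e+06	1.32e+06	1.44e+06
P06	P06	10			+	1.25e+06	1.375e+06	1.5e+06	1.625e+06	1.125e+06	1.25e+06	1.375e+06	1.5e+06	1.25e+06	1.375e+06	1.5e+06	1.625e+06	1.125e+06	1.25e+06	1.375e+06	1.5e+06
P07	P07	11				1.3e+06	1.43e+06	1.56e+06	1.69e+06	0	0	0	0	1.3e+06	1.43e+06	1.56e+06	1.69e+06	0	0	0	0
P08	P08	12				1.35e+06	1.485e+06	1.62e+06	0	1.215e+06	1.35e+06	1.485e+06	0	1.35e+06	1.485e+06	1.62e+06	0	1.215e+06	1.35e+06	1.485e+06	0
P09	P09	13				0	0	0	0	1.26e+06	1.4e+06	1.54e+06	1.68e+06	0	0	0	0	1.26e+06	1.4e+06	1.54e+06	1.68e+06
P10	P10	14				1.45e+06	1.595e+06	1.74e+06	1.885e+06	1.305e+06	1.45e+06	1.595e+06	1.74e+06	1.45e+06	1.595e+06	1.74e+06	1.885e+06	1.305e+06	1.45e+06	1.595e+06	1.74e+06
P11	P11	15				1.5e+06	1.65e+06	0	0	1.35e+06	1.5e+06	1.65e+06	1.8e+06	1.5e+06	1.65e+06	0	0	1.35e+06	1.5e+06	1.65e+06	1.8e+06
P12	P12	16				1.55e+06	0	0	0	0	0	0	0	1.55e+06	0	0	0	0	0	0	0
P13	P13	17				0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
P14	P14	18				1.65e+06	1.815e+06	1.98e+06	2.145e+06	1.485e+06	1.65e+06	1.815e+06	1.98e+06	1.65e+06	1.815e+06	1.98e+06	2.145e+06	1.485e+06	1.65e+06	1.815e+06	1.98e+06
P15	P15	19				1.7e+06	1.87e+06	2.04e+06	2.21e+06	1.53e+06	1.7e+06	1.87e+06	2.04e+06	1.7e+06	1.87e+06	2.04e+06	2.21e+06	1.53e+06	1.7e+06	1.87e+06	2.04e+06
P16	P16	20				1.75e+06	1.925e+06	2.1e+06	2.275e+06	1.575e+06	1.75e+06	1.925e+06	2.1e+06	1.75e+06	1.925e+06	2.1e+06	2.275e+06	1.575e+06	1.75e+06	1.925e+06	2.1e+06
P17	P17	21				1.8e+06	1.98e+06	2.16e+06	2.34e+06	1.62e+06	1.8e+06	1.98e+06	2.16e+06	1.8e+06	1.98e+06	2.16e+06	2.34e+06	1.62e+06	1.8e+06	1.98e+06	2.16e+06
P18	P18	22				1.85e+06	2.035e+06	2.22e+06	2.405e+06	1.665e+06	1.85e+06	2.035e+06	2.22e+06	1.85e+06	2.035e+06	2.22e+06	2.405e+06	1.665e+06	1.85e+06	2.035e+06	2.22e+06
P19	P19	23				1.9e+06	2.09e+06	2.28e+06	2.47e+06	1.71e+06	1.9e+06	2.09e+06	2.28e+06	1.9e+06	2.09e+06	2.28e+06	2.47e+06	1.71e+06	1.9e+06	2.09e+06	2.28e+06
P20	P20	24				1.95e+06	2.145e+06	2.34e+06	2.535e+06	1.755e+06	1.95e+06	2.145e+06	2.34e+06	1.95e+06	2.145e+06	2.34e+06	2.535e+06	1.755e+06	1.95e+06	2.145e+06	2.34e+06
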