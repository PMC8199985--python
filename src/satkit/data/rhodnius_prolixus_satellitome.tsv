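name	n_clusters	genome_proportion_pct	repeat_length_bp	at_pct	divergence_pct
RproSat01-165	38	2.13	165	72.1	13.42
RproSat02-169	5	1.94	169	69.2	9.81
RproSat03-124	2	1.18	124	62.1	8.81
RproSat04-133	23	0.861	133	66.2	17.38
RproSat05-208	1	0.460	208	53.4	15.48
RproSat06-136	1	0.320	136	62.5	12.42
RproSat07-375	1	0.200	375	68.5	7.77
RproSat08-67	1	0.194	67	61.2	20.58
RproSat09-499	1	0.107	499	71.1	12.20
RproSat10-104	1	0.085	104	62.5	10.10
RproSat11-198	1	0.073	198	83.3	2.23
RproSat12-41	1	0.069	41	58.5	10.03
RproSat13-293	-	0.067	293	61.1	28.28
RproSat14-461	1	0.062	461	64.2	6.19
RproSat15-161	1	0.052	161	60.9	8.38
RproSat16-821	1	0.044	821	65.3	6.83
RproSat17-584	1	0.027	584	64.7	11.71
RproSat18-122	1	0.019	122	63.1	25.27
RproSat19-201	1	0.019	201	76.1	19.52
RproSat20-134	1	0.017	134	68.7	16.23
RproSat21-167	1	0.016	167	71.3	16.25
RproSat22-980	2	0.013	980	69.4	4.75
RproSat23-412	1	0.010	412	75.2	5.59
RproSat24-673	1	0.009	673	70.0	2.89
RproSat25-84	-	0.009	84	65.5	25.75
RproSat26-146	1	0.009	146	63.7	3.55
RproSat27-187	1	0.008	187	27.8	13.06
RproSat28-199	1	0.008	199	53.8	12.72
RproSat29-31	1	0.006	31	77.4	11.21
RproSat30-201	1	0.006	201	61.2	3.02
RproSat31-75	1	0.005	75	68.0	2.64
RproSat32-59	1	0.004	59	59.3	0.88
RproSat33-123	1	0.003	123	78.0	0.96
RproSat34-415	1	0.003	415	72.8	5.15
RproSat35-279	1	0.003	279	60.6	5.71
RproSat36-40	1	0.003	40	70.0	4.17
RproSat37-98	-	0.0005	98	69.4	6.96
Telomeric repeat	-	0.003	5	60.0	13.9
(GATA)n repeat	-	0.001	4	75.0	10.1
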