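entry	qtl	DS10|non_stress	DS11|non_stress	DS10|drought	DS11|drought
IR87729-69-B-B-B	qDTY9.1;qDTY2.2;qDTY10.1;qDTY4.1	4312	6308	2011	1943
IR87728-491-B-B	qDTY9.1;qDTY2.2;qDTY4.1		6232	1041	1879
IR87707-186-B-B-B	qDTY2.2;qDTY10.1;qDTY4.1	4550	6103	2068	2632
IR87707-359-B-B-B	qDTY2.2;qDTY10.1;qDTY4.1	4638	6361	1934	2581
IR87707-446-B-B-B	qDTY2.2;qDTY4.1	3752	4388	2556	3000
IR87707-445-B-B-B	qDTY2.2;qDTY4.1	5045	5844	2555	3023
IR87707-182-B-B-B	qDTY2.2;qDTY4.1	3875	5225	1926	2891
IR87728-162-B-B	qDTY9.1;qDTY2.2		6115	1147	1636
IR87705-83-12-B	qDTY2.2;qDTY10.1	4796	5526	1916	2270
IR87705-80-15-B	qDTY10.1;qDTY4.1	3850	5516	2074	2151
IR87705-72-12-B	qDTY2.2	3569	6090	1879	1892
IR87705-6-8-B	qDTY4.1	5399	6208	2152	2588
IR87728-395-B-B	qDTY9.1		6627	2440	2046
IR87705-36-3-B	qDTY10.1	5052	6909		2116
IR64		2987	5435	636	1442
LSD			1053		690
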