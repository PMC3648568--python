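entry	Rajshahi|non_stress	Rajshahi|drought	Nepalganj|non_stress	Nepalganj|drought	Raipur|non_stress	Raipur|drought	Hyderabad 1|non_stress	Hyderabad 1|drought	Hyderabad 2|non_stress	Hyderabad 2|drought	Hazaribagh|non_stress	Hazaribagh|drought	Rewa|non_stress	Rewa|drought
IR87707-445-B-B	4167	1525	5990	3472	5084	3956	5672	1684	5672	3800	5690	1604	4100	3731
IR87707-446-B-B	4521	1933	6302	2847	5771	3614	5634	1813	5634	4057	5711	1229	4911	3899
IR87707-182-B-B	4312	1508	6510	2778	5646	3419	6047	1383	6047	3604	4453	1500	4513	3509
IR64	3379	980	4297	1597	4083	2662	5699	660	5699	3085	5612	958	3586	2503
LSD	240	156	324	170	434	285	186	939	186	600	475	422	920	909
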