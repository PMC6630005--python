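region	gene	p_ad	top_snp_ad	top_snp_ad_p	p_is	top_snp_is	top_snp_is_p	p_combined
7q34	ZYX	5.10E-04	rs6464548	1.62E-06	2.70E-05	rs11772895	3.39E-06	2.63E-07
7q34-q35	EPHA1	1.00E-06	rs10808026	1.42E-11	3.64E-02	rs11762334	7.16E-05	6.60E-07
15q25.2	EFTUD1	1.09E-04	rs905450	2.82E-06	8.24E-04	rs151045855	2.17E-04	1.55E-06
11q12.2	MS4A4A	1.50E-05	rs55777218	3.94E-12	4.21E-02	rs115739426	5.29E-03	9.65E-06
22q11.21	YDJC	2.01E-04	rs2298428	7.28E-05	1.00E-02	rs3747093	2.87E-03	2.84E-05
22q11.21	UBE2L3	2.72E-04	rs12168746	8.82E-05	7.74E-03	rs738129	3.95E-03	2.96E-05
8q22.3	PABPC1	4.76E-03	rs1693547	9.19E-04	9.00E-04	rs3104313	1.94E-04	5.72E-05
16p12.2	RRN3P1	1.56E-03	rs12600118	3.92E-05	3.62E-03	rs4017431	8.17E-04	7.39E-05
15q25.2	FAM154B	2.56E-04	rs28522807	2.86E-04	2.56E-02	rs117388641	1.55E-03	8.48E-05
17q25.1	SLC16A5	7.22E-04	rs8078881	2.32E-04	1.23E-02	rs12943414	1.70E-03	1.12E-04
12q24.13	HECTD4	3.68E-02	rs147910225	2.31E-04	2.70E-04	rs10850034	2.49E-05	1.24E-04
5q31.3	ANKHD1-EIF4EBP3	8.61E-04	rs78028717	2.52E-04	1.27E-02	rs801459	1.39E-03	1.36E-04
8p23.1	PINX1	1.23E-03	rs7014168	3.60E-04	9.20E-03	rs12676417	6.40E-04	1.40E-04
22q11.23	SLC2A11	1.12E-03	rs5760076	3.91E-05	1.06E-02	rs73158776	2.17E-03	1.47E-04
12q24.13	OAS2	2.50E-04	rs1635142	4.27E-05	4.96E-02	rs929291	8.24E-03	1.52E-04
5q31.3	ANKHD1	1.18E-03	rs78028717	2.52E-04	1.06E-02	rs2108446	1.85E-03	1.54E-04
6p21.1	TREM2	1.52E-03	rs6933067	1.07E-03	9.50E-03	rs7748513	4.34E-03	1.75E-04
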