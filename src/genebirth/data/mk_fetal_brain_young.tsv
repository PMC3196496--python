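refseq	symbol	ds	ps	dn	pn	p	u	sd
NM_133473	ZNF431	5	0	11	0	0.00102	8.61813	4.83494
NM_182492	DKFZp434O021	2	0	6	0	0.00814	7.68427	4.90936
NM_145298	APOBEC3F	0	1	11	2	0.0296	4.10728	3.49844
NM_018933	PCDHB13	1	0	2	0	0.06178	6.39172	5.06886
NM_153608	MGC17986	7	0	8	2	0.08628	3.18396	3.28736
NM_033213	MGC12466	0	0	1	0	0.13642	5.36558	5.53891
NM_001700	AZU1	1	3	1	0	0.13726	5.35647	5.58777
NM_024341	ZNF557	2	0	3	1	0.16624	3.58025	4.13862
NM_020880	ZNF530	4	0	3	1	0.16678	3.56122	4.0604
NM_178861	ZNF183L1	1	2	2	1	0.27246	2.70492	4.17857
NM_005364	MAGEA8	1	2	3	2	0.44028	1.00461	2.8012
NM_018260	FLJ10891	0	1	1	1	0.53468	0.056067	5.14113
NM_033204	ZNF101	5	0	3	4	0.8654	-1.12073	1.47848
NM_207393	IGFL3	0	1	0	1	0.907	-6.04225	5.56359
NM_000200	HTN3	0	1	0	2	0.98504	-7.36289	4.7631
NM_015703	CGI-96	2	1	0	3	0.99682	-7.76714	4.63335
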