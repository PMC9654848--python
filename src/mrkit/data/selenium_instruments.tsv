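snp_id	gene	chrom	effect_allele	other_allele	eaf	beta_exp	se_exp	p_exp	zscore	f_stat	r2	beta_egfr	se_egfr	p_egfr	beta_bun	se_bun	p_bun
rs672413	ARSB	5	A	G	0.32	0.164418	0.021835	5.21e-14	7.53	114.728	0.011765	-0.0012	0.0003	6.91e-5	0.0006	0.0005	0.2719
rs705415	DMGDH	5	T	C	0.14	-0.20006	0.032113	4.64e-10	-6.23	78.36179	0.009638	0.0008	0.0004	0.0541	-0.0004	0.0008	0.6377
rs3797535	DMGDH	5	T	C	0.08	0.298102	0.037544	2.05e-15	7.94	127.7319	0.013081	-0.0008	0.0005	0.1122	0.0009	0.001	0.3606
rs11951068	DMGDH	5	A	G	0.07	0.268264	0.03992	1.86e-11	6.72	91.15215	0.00937	-0.0014	0.0005	0.008477	-0.0002	0.0008	0.7902
rs921943	DMGDH	5	T	C	0.29	0.294952	0.022447	1.90e-39	13.14	358.0757	0.035825	-0.0021	0.0003	2.62e-12	0.001	0.0005	0.05763
rs10944	BHMT2	5	T	G	0.49	0.257746	0.020375	1.13e-36	12.65	330.9678	0.033203	-0.0012	0.0003	6.42e-6	0.0012	0.0005	0.01758
rs567754	BHMT	5	T	C	0.34	-0.19588	0.021502	8.38e-20	-9.11	168.8575	0.01722	0.0008	0.0003	0.005016	-0.0016	0.0005	3.21e-3
rs6859667	HOMER1	5	T	C	0.96	-0.35969	0.051978	4.40e-12	-6.92	96.71387	0.009936	0.001	0.0007	0.1318	-0.0017	0.0013	0.1955
rs6586282	CBS	21	T	C	0.17	-0.15971	0.027116	3.96e-9	-5.89	69.87277	0.007198	0.0011	0.0004	0.00323	0.0004	0.0007	0.5388
rs1789953	CBS	21	T	C	0.14	0.162035	0.029354	3.40e-8	5.52	61.31581	0.006322	-0.0002	0.0004	0.6217	-0.0018	0.0008	0.02094
rs234709	CBS	21	T	C	0.45	-0.11957	0.020474	5.23e-9	-5.84	68.68309	0.007077	0.0001	0.0003	0.7589	0.0004	0.0005	0.4208
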