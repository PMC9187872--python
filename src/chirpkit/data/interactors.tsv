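uniprot_id	gene_name	neg_log10_p	log2_ratio	exclusive	compartment
Q7JJ13	Brd2	3.44	-1.27	No	none
Q8R149	Bud13	3.20	-1.61	No	none
O35658	C1qbp	3.66	-2.06	No	none
Q9JJ89	Ccdc86	4.79	-1.55	No	none
Q99LM2	Cdk5rap3	2.73	-1.51	No	none
Q8K327	Champ1	4.35	-1.52	No	none
Q921N6	Ddx27	5.15	-2.14	No	Nucleolus
O08749	Dld	6.00	-2.13	No	none
Q9D2G2	Dlst	3.57	-2.49	No	none
O08579	Emd	4.27	-2.69	No	Nuclear lamin
O35130	Emg1	5.19	-1.08	No	Nucleolus
P62806	Hist1h4a	3.63	-1.98	No	none
Q9DC33	Hmg20a	4.31	-2.16	No	none
P38647	Hspa9	6.57	-1.99	No	none
Q3U9G9	Lbr	2.92	-2.71	No	Nuclear lamin
P48678	Lmna	5.43	-1.18	No	Nuclear lamin
P14733	Lmnb1	5.63	-3.73	No	Nuclear lamin
P21619	Lmnb2	4.90	-3.00	No	Nuclear lamin
Q6PB66	Lrpprc	3.00	-2.05	No	none
Q810V0	Mphosph10	3.71	-2.72	No	Nucleolus
Q91VE6	Nifk	4.00	-1.67	No	Nucleolus
Q9WV70	Noc2l	2.99	-1.26	No	Nucleolus
Q8BH74	Nup107	3.23	-1.14	No	Nuclear pore
Q8R0G9	Nup133	3.34	-1.70	No	Nuclear pore
Q9CWU9	Nup37	4.06	-2.31	No	Nuclear pore
P59235	Nup43	6.28	-2.93	No	Nuclear pore
Q9JIH2	Nup50	5.74	-1.13	No	Nuclear pore
Q8BTS4	Nup54	4.34	-3.37	No	Nuclear pore
Q8R480	Nup85	3.47	-1.98	No	Nuclear pore
Q8BJ71	Nup93	4.32	-3.14	No	Nuclear pore
Q6PFD9	Nup98	5.50	-2.68	No	Nuclear pore
Q8R332	Nupl1	4.88	-3.66	No	Nuclear pore
P67778	Phb	4.68	-2.54	Yes	none
O35129	Phb2	5.75	-2.48	Yes	none
Q9WTU0	Phf2	3.19	-1.48	No	none
Q8R3C6	Rbm19	4.06	-1.51	No	none
Q9JJT0	Rcl1	3.08	-1.63	No	Nucleolus
Q91WM3	Rrp9	5.44	-1.36	No	Nucleolus
Q9CYH6	Rrs1	3.75	-1.45	No	Nucleolus
Q8R2U0	Seh1l	3.23	-1.82	No	Nuclear pore
Q91ZW3	Smarca5	3.74	-1.30	No	none
Q8C4J7	Tbl3	3.78	-1.41	No	Nucleolus
Q9CR67	Tmem33	4.45	-3.17	No	none
Q921T2	Tor1aip1	4.20	-1.88	Yes	Nuclear lamin
Q9JI13	Utp3	4.54	-2.11	Yes	Nucleolus
Q9JJA4	Wdr12	3.75	-1.37	No	Nucleolus
Q8BHB4	Wdr3	3.22	-1.55	No	Nucleolus
Q6ZQL4	Wdr43	2.95	-1.40	No	Nucleolus
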