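variant_id	exon	class	genomic_location	cdna_change	af	cadd	revel	clinvar	case_count
p.L4P	1	missense	8-90996779-A-G	c.T11C	0	24.6	0.462	VUS	2
p.L18I	2	missense	8-90995069-G-T	c.C52A	1.41E-05	24	0.158	VUS	1
p.Q39K	2	missense	8-90995006-G-T	c.C115A	0	24	0.542	VUS	1
p.S40L	2	missense	8-90995002-G-A	c.C119T	1.19E-05	27	0.88	VUS	2
p.S93L	3	missense	8-90993645-G-A	c.C278T	5.81E-04	25	0.457	VUS*	2
p.M152I	4	missense	8-90992986-C-T	c.G456A	1.13E-04	27.3	0.482	VUS*	7
p.K156N	4	missense	8-90992974-T-G	c.A468C	1.51E-04	26.1	0.438	VUS*	3
p.E179K	5	missense	8-90990497-C-T	c.G535A	3.98E-06	32	0.308	VUS	1
p.V184A	5	missense	8-90990481-A-G	c.T551C	0	25.2	0.179	VUS	1
p.E217Q	6	missense	8-90983454-C-G	c.G649C	7.97E-06	25.1	0.224	VUS	1
p.K219fs	6	frameshift	8-90983441-ATTTGT-A	c.657_661del	2.02E-04	32	NA	Pathogenic	7
p.F222L	6	missense	8-90983439-A-G	c.T664C	1.77E-05	28.2	0.937	VUS	1
p.I228R	6	missense	8-90983420-A-C	c.T683G	7.10E-05	25.7	0.54	VUS	3
p.A241T	7	missense	8-90982767-C-T	c.G721A	1.59E-05	26	0.396	VUS	1
p.F263S	7	missense	8-90982700-A-G	c.T788C	1.95E-04	25.4	0.737	VUS*	2
p.G274R	7	missense	8-90982668-C-T	c.G820A	7.96E-06	24	0.308	VUS	1
p.L281X	7	stop_gain	8-90982646-A-C	c.T842G	3.98E-06	33	NA	Pathogenic	1
p.A313V	8	missense	8-90976694-G-A	c.C938T	3.18E-05	26.8	0.661	VUS	1
p.Q448L	10	missense	8-90967565-T-A	c.A1343T	4.25E-05	21.5	0.037	VUS*	1
p.D469Y	11	missense	8-90965912-C-A	c.G1405T	6.16E-05	26.1	0.149	VUS*	1
p.P495L	11	missense	8-90965833-G-A	c.C1484T	3.19E-05	23.9	0.097	VUS	1
p.E552Q	11	missense	8-90965663-C-G	c.G1654C	0	23.6	0.058	VUS	1
p.V556E	11	missense	8-90965650-A-T	c.T1667A	1.99E-05	22.5	0.078	VUS	2
p.E564K	11	missense	8-90965627-C-T	c.G1690A	8.10E-04	22.9	0.081	Benign/Likely benign	5
p.S706X	14	stop_gain	8-90955548-G-C	c.C2117G	1.06E-05	42	NA	Pathogenic	1
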