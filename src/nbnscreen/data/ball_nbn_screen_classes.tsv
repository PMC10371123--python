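variant_id	residue	stability_class	mmc_class	reported_call
p.L4P	4	complete_loss	high	pathogenic
p.S40L	40	complete_loss	high	pathogenic
p.S706X	706	complete_loss	high	pathogenic
p.I228R	228	complete_loss	high	pathogenic
p.A313V	313	complete_loss	high	pathogenic
p.K219fs	219	complete_loss	high	pathogenic
p.L281X	281	complete_loss	high	pathogenic
p.F222L	222	partial_loss	moderate	likely_pathogenic
p.M152I	152	partial_loss	wt_like	likely_pathogenic
p.S93L	93	partial_loss	moderate	likely_pathogenic
p.K156N	156	partial_loss	moderate	likely_pathogenic
p.E179K	179	partial_loss	wt_like	likely_pathogenic
p.V184A	184	partial_loss	wt_like	likely_pathogenic
p.Q39K	39	wt_like	moderate	likely_pathogenic
p.F263S	263	mild_loss	wt_like	likely_benign
p.E217Q	217	mild_loss	wt_like	likely_benign
p.A241T	241	mild_loss	wt_like	likely_benign
p.L18I	18	mild_loss	wt_like	likely_benign
p.P495L	495	wt_like	wt_like	likely_benign
p.E552Q	552	wt_like	wt_like	likely_benign
p.G274R	274	wt_like	wt_like	likely_benign
p.Q448L	448	wt_like	wt_like	likely_benign
p.D469Y	469	wt_like	wt_like	likely_benign
p.E564K	564	wt_like	wt_like	likely_benign
p.V556E	556	wt_like	wt_like	likely_benign
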