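# Genotype-versus-phenotype screening table: the IQCB1 deletion plus the
# seven moderate-impact missense candidates, across the 15 cats genotyped
# by mass-spectrometry assay.  Transcribed from the published table; the
# alternate allele of each missense column is declared as the allele
# homozygous in the whole-genome-sequenced affected cat (247).
sample	sex	phenotype	IQCB1:wt>delCT	CHD3:A>G	CNGB1:C>T	DTHD1_942:C>G	RBP3:G>A	USH1C:C>T	CDH23:C>T	DTHD1_144:A>C
247	F	affected	delCT/delCT	GG	TT	GG	AA	TT	TT	CC
205	M	normal	wt/delCT	AG	CT	GC	AG	CT	CT	CA
208	F	normal	wt/delCT	AG	CT	GC	AG	CT	CT	CA
235	M	affected	delCT/delCT	AA	CC	GG	AG	CT	TT	CC
240	M	normal	wt/delCT	AA	CT	GG	GG	CT	CT	CA
248	F	normal	wt/delCT	/	CC	/	AG	TT	CC	/
258	M	normal	wt/delCT	AA	TT	GC	GG	CC	CC	AA
236	M	normal	wt/wt	AA	CC	GC	AG	CT	CT	CA
230	M	normal	wt/wt	AA	CC	CC	GG	CC	CC	AA
234	F	normal	wt/wt	/	/	CC	GG	/	/	AA
251	F	normal	wt/wt	AA	CC	CC	GG	CC	CT	AA
229	M	normal	wt/wt	AA	CC	CC	GG	CT	CC	AA
222	F	normal	wt/wt	AA	CT	CC	GG	TT	CT	AA
233	F	normal	wt/wt	AA	CC	CC	GG	TT	CC	CA
223	F	normal	wt/wt	AA	CC	GC	GG	CT	CC	CA
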