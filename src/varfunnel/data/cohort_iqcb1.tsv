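# Screening cohort of 16 captive black-footed cats: IQCB1 c.1282delCT
# genotypes from direct sequencing.  Transcribed from the published
# studbook screening table.
sample	sex	phenotype	IQCB1:wt>delCT
205	M	normal	wt/delCT
208	F	normal	wt/delCT
222	F	normal	wt/wt
223	F	normal	wt/wt
228	M	normal	wt/delCT
229	M	normal	wt/wt
230	M	normal	wt/wt
233	F	normal	wt/wt
234	F	normal	wt/wt
235	M	affected	delCT/delCT
236	M	normal	wt/wt
240	M	normal	wt/delCT
247	F	affected	delCT/delCT
248	F	normal	wt/delCT
251	F	normal	wt/wt
258	M	normal	wt/delCT
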