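# Studbook pedigree of the captive black-footed cat population, transcribed
# from the published pedigree figure.  The figure is not machine-readable;
# this transcription preserves the facts the text states (obligate carrier
# parents 205 and 208, the affected cats 235 and 247 and their genotyped
# siblings, the unrelated wild-type lineage containing 222 and 223, the
# carrier crosses producing the ungenotyped litters 260-262 and 264-266)
# without claiming edge-level fidelity for the remainder.
# columns: family individual sire dam sex phenotype
BFC	205	0	0	1	1
BFC	208	0	0	2	1
BFC	209	205	208	0	0
BFC	228	205	208	1	1
BFC	235	205	208	1	2
BFC	236	205	208	1	1
BFC	240	205	208	1	1
BFC	247	205	208	2	2
BFC	248	205	208	2	1
BFC	258	205	208	1	1
BFC	206	0	0	1	0
BFC	207	0	0	2	0
BFC	210	0	0	1	0
BFC	211	0	0	2	0
BFC	222	206	207	2	1
BFC	223	206	207	2	1
BFC	229	206	207	1	1
BFC	230	206	207	1	1
BFC	233	210	211	2	1
BFC	234	210	211	2	1
BFC	251	210	211	2	1
BFC	263	230	251	0	0
BFC	231	0	0	2	0
BFC	260	228	231	1	0
BFC	261	228	231	2	0
BFC	262	228	231	0	0
BFC	250	0	0	1	0
BFC	264	250	248	1	0
BFC	265	250	248	2	0
BFC	266	250	248	0	0
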