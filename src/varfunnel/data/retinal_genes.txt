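# Synthetic illustrative list of genes associated with retinal disease,
# standing in for a user-supplied curated database.  One symbol per line.
IQCB1
CDH23
CNGB1
RBP3
USH1C
DTHD1
CHD3
RASGRF1
CCDC114
CEP290
CRX
AIPL1
RPE65
RPGR
NPHP4
PDE6B
RHO
ABCA4
PRPH2
CNGA1
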