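# weighted burden scheme: MAF parabola and annotation weights
maf_cap 0.01
w_at_zero 10
w_at_cap 1
base intronic_etc 1
base utr5 1
base synonymous 1
base splice_region 20
base utr3 1
base protein_altering 5
base inframe_indel 10
base lof 100
polyphen possibly_damaging 5
polyphen probably_damaging 10
sift deleterious 20
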