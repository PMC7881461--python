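##fileformat=VCFv4.2
##contig=<ID=locus,length=2000>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
locus	1001	.	A	G	.	.	.
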