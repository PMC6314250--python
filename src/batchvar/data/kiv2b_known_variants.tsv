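pos	ref	alt	label	alias
594	A	G	KIV-2B canonical	exon1 14A>G
621	T	C	KIV-2B canonical	exon1 41T>C
666	A	T	KIV-2B canonical	exon1 86A>T
2106	G	A	named variant	DraIII site-creating 2106G>A
4925	G	A	named variant	4925G>A
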