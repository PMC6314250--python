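name	type	start	end	frame_offset	order_index
# default element annotation of the 5104 bp repeat-unit amplicon.
# exon1 coordinates follow from the canonical subtype-defining positions
# (exon offsets 14/41/86 -> amplicon 594/621/666); the exon2 start is
# provisional (set so the exon spans 182 bp ending at 4925) and should be
# overridden by a curated annotation where available.
exon421	exon	581	740	2	1
intron	intron	741	4743	.	.
exon422	exon	4744	4925	1	2
microsatellite	microsatellite	2472	2505	.	.
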