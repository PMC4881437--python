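chrom	arm	start	end
chr1	p	0	60000000
chr1	q	60000000	140000000
chr2	p	0	50000000
chr2	q	50000000	120000000
chr3	p	0	40000000
chr3	q	40000000	100000000
chr4	p	0	30000000
chr4	q	30000000	90000000
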