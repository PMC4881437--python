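dataset	platform_note	n_tumor	n_normal
GSE10961	liver metastases from CRC	18	0
GSE13067	primary colorectal tumors	74	0
GSE13294	primary CRCs	155	0
GSE14333	primary CRCs	290	0
GSE15960	colon adenomas and CRCs	12	6
GSE17536	CRCs	177	0
GSE17537	metastatic CRCs	55	0
GSE18088	stage II CRCs	53	0
GSE18105	stage II and III CRCs	77	34
GSE20916	colon adenomas and CRCs	101	44
GSE23878	CRCs	35	24
GSE24514	MSI CRCs	34	15
GSE26682	MSI CRCs	331	0
GSE31595	stage II and III CRCs	37	0
GSE33113	primary stage II CRCs	90	0
GSE35896	primary CRC tumors	62	0
GSE4045	serrated and conventional colorectal adenocarcinomas	37	0
GSE5851	metastatic CRCs	80	0
GSE8671	colorectal adenomas	32	32
GSE9348	early stage CRC tumors	70	12
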