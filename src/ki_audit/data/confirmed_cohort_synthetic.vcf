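##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##contig=<ID=chr10>
##contig=<ID=chr11>
##contig=<ID=chr1>
##contig=<ID=chr2>
##contig=<ID=chr3>
##contig=<ID=chr4>
##contig=<ID=chr5>
##contig=<ID=chr6>
##contig=<ID=chr7>
##contig=<ID=chr8>
##contig=<ID=chr9>
##contig=<ID=chr12>
##contig=<ID=chr13>
##contig=<ID=chr14>
##contig=<ID=chr15>
##contig=<ID=chr16>
##contig=<ID=chr17>
##contig=<ID=chr18>
##contig=<ID=chr19>
##contig=<ID=chrX>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	268-1	283-1	306-1	316-2	B6J
chr10	60123456	.	A	ACT	.	.	GENE=Zfp365;EFFECT=insertion	GT:DP:AD	0/0:107:107,0	0/0:123:123,0	0/0:102:102,0	0/1:107:46,61	0/0:97:97,0
chr11	70254321	.	CTGAGGATCCAGGTTCAA	C	.	.	GENE=Alox12;EFFECT=deletion	GT:DP:AD	0/0:124:124,0	0/1:120:66,54	0/0:104:104,0	0/0:104:104,0	0/0:121:121,0
chr11	82012345	.	G	GTCC	.	.	GENE=Aspa;EFFECT=insertion	GT:DP:AD	0/0:116:116,0	0/1:103:46,57	0/0:116:116,0	0/0:97:97,0	0/0:105:105,0
chr1	20000572	.	C	T	.	.	GENE=Gm5101;EFFECT=missense	GT:DP:AD	0/1:103:47,56	0/0:106:106,0	0/0:98:98,0	0/0:102:102,0	0/0:96:96,0
chr2	23456934	.	G	C	.	.	GENE=Gm5102;EFFECT=missense	GT:DP:AD	0/1:118:62,56	0/0:121:121,0	0/0:98:98,0	0/0:96:96,0	0/0:122:122,0
chr3	26914186	.	C	T	.	.	GENE=Gm5103;EFFECT=missense	GT:DP:AD	0/1:102:47,55	0/0:113:113,0	0/0:110:110,0	0/0:103:103,0	0/0:123:123,0
chr4	30371240	.	T	C	.	.	GENE=Gm5104;EFFECT=missense	GT:DP:AD	0/1:112:65,47	0/0:103:103,0	0/0:107:107,0	0/0:100:100,0	0/0:112:112,0
chr5	33828038	.	C	A	.	.	GENE=Gm5105;EFFECT=missense	GT:DP:AD	0/0:101:101,0	0/1:124:68,56	0/0:104:104,0	0/0:122:122,0	0/0:124:124,0
chr6	37284149	.	T	C	.	.	GENE=Gm5106;EFFECT=missense	GT:DP:AD	0/0:123:123,0	0/1:108:54,54	0/0:109:109,0	0/0:98:98,0	0/0:115:115,0
chr7	40741049	.	G	C	.	.	GENE=Gm5107;EFFECT=missense	GT:DP:AD	0/0:105:105,0	0/1:97:57,40	0/0:104:104,0	0/0:119:119,0	0/0:98:98,0
chr8	44197910	.	T	G	.	.	GENE=Gm5108;EFFECT=missense	GT:DP:AD	0/0:106:106,0	0/1:122:67,55	0/0:101:101,0	0/0:106:106,0	0/0:115:115,0
chr9	47654470	.	T	C	.	.	GENE=Gm5109;EFFECT=missense	GT:DP:AD	0/0:114:114,0	0/1:107:59,48	0/0:113:113,0	0/0:112:112,0	0/0:98:98,0
chr12	51111327	.	C	T	.	.	GENE=Gm5110;EFFECT=missense	GT:DP:AD	0/0:122:122,0	0/0:117:117,0	0/1:108:59,49	0/0:123:123,0	0/0:117:117,0
chr13	54567903	.	C	G	.	.	GENE=Gm5111;EFFECT=missense	GT:DP:AD	0/0:121:121,0	0/0:117:117,0	0/1:124:54,70	0/0:116:116,0	0/0:111:111,0
chr14	58025261	.	T	G	.	.	GENE=Gm5112;EFFECT=missense	GT:DP:AD	0/0:114:114,0	0/0:114:114,0	0/1:114:63,51	0/0:101:101,0	0/0:120:120,0
chr15	61482147	.	C	A	.	.	GENE=Gm5113;EFFECT=missense	GT:DP:AD	0/0:97:97,0	0/0:107:107,0	0/0:107:107,0	0/1:101:48,53	0/0:107:107,0
chr16	64938361	.	G	T	.	.	GENE=Gm5114;EFFECT=missense	GT:DP:AD	0/0:123:123,0	0/0:100:100,0	0/0:98:98,0	0/1:114:53,61	0/0:100:100,0
chr17	68395603	.	A	C	.	.	GENE=Gm5115;EFFECT=missense	GT:DP:AD	0/0:99:99,0	0/0:118:118,0	0/0:98:98,0	0/1:108:61,47	0/0:97:97,0
chr18	71852576	.	A	C	.	.	GENE=Gm5116;EFFECT=missense	GT:DP:AD	0/0:102:102,0	0/0:97:97,0	0/0:124:124,0	0/1:103:51,52	0/0:109:109,0
chr19	75308963	.	C	T	.	.	GENE=Gm5117;EFFECT=nonsense	GT:DP:AD	0/0:102:102,0	0/0:113:113,0	0/0:121:121,0	0/0:123:123,0	0/1:121:56,65
chrX	78766408	.	T	C	.	.	GENE=Gm5118;EFFECT=splice_donor	GT:DP:AD	0/0:111:111,0	0/0:109:109,0	0/0:123:123,0	0/0:103:103,0	0/1:106:49,57
chr1	82223149	.	G	C	.	.	GENE=Gm5119;EFFECT=missense	GT:DP:AD	0/0:123:123,0	0/0:107:107,0	0/0:121:121,0	0/0:115:115,0	0/1:101:45,56
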