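family	group	nc	fop	gc3s	noncoding_gc	copy_number	copy_number_fle	expression_reads
Sroscv1	chromovirus	49.12	0.569	0.634	0.486	16	8	457
Sroscv2	chromovirus	45.22	0.598	0.627	0.450	7	4	243
Sroscv3	chromovirus	55.48	0.526	0.594	0.494	21	10	1288
Sroscv4	chromovirus	42.06	0.694	0.763	0.552	15	12	92
Sroscv5	chromovirus	46.35	0.620	0.701	0.485	9	6	1591
Srosgyp1	gypsy_nonchromo	40.27	0.698	0.791	0.492	9	6	197
Srosgyp2	gypsy_nonchromo	40.10	0.672	0.768	0.541	6	6	4856
Srospv1	copia	46.84	0.603	0.682	0.491	14	11	327
Srospv2	copia	38.05	0.729	0.784	0.497	71	41	4211
Srospv3	copia	37.03	0.746	0.805	0.489	121	59	5182
Srospv4	copia	48.09	0.450	0.570	0.483	4	1	48
Srospv5	copia	49.28	0.550	0.641	0.466	3	2	1082
SrosH	transposon	45.17	0.615	0.740	0.555	7	7	1402
SrosHar	transposon	58.55	0.448	0.530	0.514	1	1	1
SrosM	transposon	55.00	0.522	0.620	0.540	23	23	19480
SrosS	transposon	50.80	0.565	0.654	0.529	2	2	7946
SrosTig1	transposon	54.90	0.505	0.578	0.483	9	9	6941
SrosTig2	transposon	52.47	0.488	0.578	0.517	5	5	78
SrosTm	transposon	49.61	0.612	0.709	0.486	11	11	15354
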