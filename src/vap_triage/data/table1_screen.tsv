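# Retinal-degeneration suppressor screen, line-level transcription.
# 52 su(rdgB) genes with their RNAi line IDs (VDRC KK/GD, Bloomington
# TRiP) and per-line suppression grades (++ definite, + partial); three
# genes had no second RNAi line available. ERG outcomes per line are
# reconstructed from the genes named in the results (5 consistently
# lower, 1 consistently higher, 2 rough-eye in both lines, 4 rough-eye
# then lower). norpA: the five named members of the 13 norpA-positive
# effectors are flagged from the text; the remaining 8 flags are
# synthetic placeholders drawn from the RNA/DNA-binding classes so the
# class totals (13 effectors / 39 trigger-specific) are preserved.
gene	line_id	source	suppression	viable	norpA	erg
CG8069	100778	KK	++	True	No	normal
CG8069	28189	GD	++	True	No	normal
CG4548	101568	KK	++	True	Yes	normal
CG4548	10618	GD	++	True	Yes	normal
CG7961	35305	GD	++	True	No	normal
CG7961	35306	GD	+	True	No	normal
CG7843	106344	KK	+	True	No	rough_eye
CG7843	22574	GD	+	True	No	lower
CG42665	105885	KK	+	True	No	normal
CG42665	101144	KK	+	True	No	normal
CG8092	28196	GD	+	True	No	normal
CG8092	25971	TRiP	+	True	No	normal
CG42458	106608	KK	++	True	Yes	normal
CG42458	108072	KK	++	True	Yes	normal
CG42522	33370	TRiP	++	True	No	normal
CG1677	109697	KK	++	True	Yes	normal
CG1677	50195	GD	+	True	Yes	normal
CG14443	105254	KK	++	True	Yes	normal
CG14443	17618	GD	++	True	Yes	normal
CG1542	104575	KK	++	True	Yes	normal
CG1542	39976	GD	++	True	Yes	normal
CG9825	105868	KK	++	True	No	normal
CG9825	1712	GD	++	True	No	normal
CG9205	107612	KK	+	True	No	lower
CG9205	29079	GD	++	True	No	lower
CG7971	101384	KK	++	True	Yes	normal
CG7971	34262	GD	+	True	Yes	normal
CG4799	102627	KK	+	True	No	normal
CG4799	32466	GD	++	True	No	normal
CG9915	103731	KK	++	True	Yes	normal
CG13849	103738	KK	+	True	Yes	normal
CG13849	51775	GD	+	True	Yes	normal
CG9181	108888	KK	++	True	No	normal
CG9181	37436	GD	++	True	No	normal
CG4396	101508	KK	+	True	No	normal
CG4396	48891	GD	+	True	No	normal
CG33967	106507	KK	++	True	No	normal
CG33967	100765	KK	++	True	No	normal
CG13176	39769	GD	++	True	No	normal
CG13176	24642	GD	++	True	No	normal
CG3071	107206	KK	++	True	No	higher
CG3071	29589	GD	+	True	No	higher
CG1598	110555	KK	+	True	No	normal
CG1598	32391	GD	++	True	No	normal
CG40218	102960	KK	++	True	No	lower
CG4697	34308	GD	++	True	No	normal
CG4697	34307	GD	++	True	No	normal
CG14444	110729	KK	++	True	No	lower
CG14444	17622	GD	++	True	No	lower
CG2890	105399	KK	++	True	No	normal
CG2890	25445	GD	++	True	No	normal
CG7283	109345	KK	++	True	Yes	rough_eye
CG7283	23459	GD	++	True	Yes	rough_eye
CG2807	110091	KK	+	True	Yes	rough_eye
CG2807	25162	GD	++	True	Yes	rough_eye
CG6538	110569	KK	+	True	Yes	normal
CG6538	12602	GD	+	True	Yes	normal
CG18332	101516	KK	+	True	No	normal
CG18332	12821	GD	++	True	No	normal
CG6379	103723	KK	+	True	Yes	rough_eye
CG6379	29611	GD	++	True	Yes	lower
CG1427	105727	KK	+	True	No	rough_eye
CG1427	17456	GD	++	True	No	lower
CG10275	106680	KK	++	True	No	normal
CG10275	37283	GD	++	True	No	normal
CG2790	101619	KK	+	True	No	normal
CG2790	20903	GD	+	True	No	normal
CG10415	100572	KK	+	True	No	normal
CG10415	12592	GD	+	True	No	normal
CG11228	104169	KK	++	True	No	normal
CG11228	7823	GD	+	True	No	normal
CG1091	107175	KK	+	True	No	normal
CG1091	16088	GD	++	True	No	normal
CG33106	103411	KK	++	True	No	normal
CG33106	33394	GD	+	True	No	normal
CG33208	105837	KK	+	True	No	normal
CG33208	25371	GD	+	True	No	normal
CG15224	106845	KK	+	True	No	normal
CG15224	32377	GD	+	True	No	normal
CG17593	106469	KK	++	True	No	normal
CG17593	13029	GD	++	True	No	normal
CG33017	103968	KK	+	True	No	normal
CG33017	40022	GD	+	True	No	normal
CG4299	108987	KK	+	True	No	lower
CG4299	77433	TRiP	+	True	No	lower
CG7207	103563	KK	++	True	No	lower
CG7207	27914	GD	+	True	No	lower
CG4202	103352	KK	++	True	Yes	normal
CG4202	49946	GD	+	True	Yes	normal
CG9977	106749	KK	++	True	No	normal
CG9977	36193	GD	++	True	No	normal
CG32847	104294	KK	++	True	No	normal
CG32847	48423	GD	++	True	No	normal
CG7839	105979	KK	+	True	No	normal
CG7839	12691	GD	+	True	No	normal
CG7483	108580	KK	++	True	No	rough_eye
CG7483	32444	TRiP	+	True	No	lower
CG9556	48044	GD	++	True	No	normal
CG9556	28908	TRiP	++	True	No	normal
CG3825	107545	KK	+	True	No	normal
CG3825	33011	TRiP	+	True	No	normal
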