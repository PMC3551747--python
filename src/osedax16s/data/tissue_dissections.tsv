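# Ribotype amplifications from five dissected tissue compartments of 21 large
# worms (7 from dive T1119, Aug-07; 14 from dive DR12, Mar-09).
# Cell dialect: "-" tissue not dissected; "na" dissected, no amplification;
# commas separate independently examined ovisac lobes; "+" joins ribotypes
# co-occurring within one lobe.
dive	bone_no	worm_no	basal_trunk	anterior_ovisac	outer_ovisac	inner_ovisac	posterior_ovisac_root
T1119		1	na	3	3	3	3
T1119		2	na	na	3	3, 3 + 29	3
T1119		4	13 + 30	13	13	13	13
T1119		5	3	3	3	na	3
T1119		7	3	3	3	3, 3	3
T1119		8	na	3	3	3	na
T1119		9	na	na	na	na	3
DR12	1	1	na	-	10	9	-
DR12	1	2	-	-	10	10	10
DR12	1	5	10	10	-	10	-
DR12	1	10	11 + 12	11	-	11	12
DR12	1	11	na	3	-	3, 3, 3	3
DR12	1	14	na	-	11	11	11
DR12	1	15	na	-	-	3, 3, na	3
DR12	1	16	na	9	-	na	9
DR12	2	1	na	10	-	-	10
DR12	2	2	na	10	-	-	10
DR12	2	3	9	9	-	-	9
DR12	2	7	na	3	-	3	3
DR12	2	10	9	9	-	9	9
DR12	2	11	13	13	-	-	13
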