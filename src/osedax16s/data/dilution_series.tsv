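# Empirical dilution-series calls: nucleotide called at each polymorphic
# position for two-template mixtures at stepped ratios (first:second, %).
# Two-fold IUPAC codes mark ratios at which both templates were detected.
mixture	replicate	position	0:100	10:90	20:80	30:70	40:60	50:50	60:40	70:30	80:20	90:10	100:0
AxB	1	666	C	C	C	Y	Y	Y	Y	T	T	T	T
AxB	2	666	C	C	C	Y	Y	Y	Y	T	T	T	T
AxB	3	666	C	C	C	Y	Y	Y	Y	T	T	T	T
CxD	1	366	A	A	R	R	R	R	R	G	G	G	G
CxD	2	366	A	A	R	R	R	R	G	G	G	G	G
CxD	3	366	A	A	R	R	R	R	G	G	G	G	G
ExF	1	120	T	T	T	W	W	W	W	W	A	A	A
ExF	2	120	T	T	T	W	W	W	W	W	A	A	A
ExF	3	120	T	T	T	W	W	W	W	W	A	A	A
ExF	1	363	A	A	A	R	R	R	R	R	G	G	G
ExF	2	363	A	A	A	R	R	R	R	R	G	G	G
ExF	3	363	A	A	A	R	R	R	R	R	G	G	G
ExF	1	660	G	G	G	G	S	S	S	S	C	C	C
ExF	2	660	G	G	G	G	S	S	S	S	C	C	C
ExF	3	660	G	G	G	G	S	S	S	S	C	C	C
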