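species	p57	p60	p66	p84	p85	p90	p91	p92	p97	p103	p111	p121	p126	p132	p138	p142	p147	p150	p157	p168	p174
Carcharodon carcharias	T	A	T	A	G	A	A	C	C	C	C	C	T	A	C	C	A	T	A	T	G
Carcharhinus longimanus	C	A	T	A	G	A	A	C	C	C	T	C	G	T	A	T	A	T	A	A	A
Cetorhinus maximus	T	A	T	A	G	G	A	C	C	C	T	T	C	C	A	C	T	T	A	T	G
Lamna nasus	T	A	T	A	G	A	A	C	C	C	T	C	T	K	C	C	C	C	A	T	A
Rhincodon typus	T	A	T	A	G	T	C	T	C	C	T	C	C	T	T	T	A	T	A	G	A
Sphyrna lewini	C	A	T	A	A	A	A	C	C	Y	T	C	A	A	T	T	A	T	A	A	A
Sphyrna mokarran	C	A	T	A	G	A	A	C	C	C	T	C	G	A	C	T	A	T	A	A	A
Sphyrna zygaena	C	A	T	A	G	G	A	C	C	C	T	C	R	A	T	C	A	T	A	A	A
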