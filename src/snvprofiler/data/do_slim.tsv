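# Synthetic reconstruction of a Disease Ontology cancer slim: fine cancer
# terms collapse onto the broader DO terms used for pan-cancer analysis.
term	collapsed_term
DOID:234	DOID:9256
DOID:1996	DOID:9256
DOID:219	DOID:9256
DOID:9256	DOID:9256
DOID:3459	DOID:1612
DOID:1612	DOID:1612
DOID:5746	DOID:2394
DOID:2394	DOID:2394
DOID:2871	DOID:363
DOID:9460	DOID:363
DOID:363	DOID:363
DOID:4467	DOID:263
DOID:4465	DOID:263
DOID:263	DOID:263
DOID:8923	DOID:1909
DOID:1909	DOID:1909
DOID:684	DOID:686
DOID:686	DOID:686
DOID:9119	DOID:74
DOID:50745	DOID:74
DOID:74	DOID:74
DOID:1324	DOID:1324
DOID:11054	DOID:11054
DOID:8557	DOID:8557
DOID:1793	DOID:1793
DOID:10534	DOID:10534
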