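channel	reporter_mz	plex
126	126.127726	10,11
127N	127.124761	10,11
127C	127.131081	10,11
128N	128.128116	10,11
128C	128.134436	10,11
129N	129.131471	10,11
129C	129.137790	10,11
130N	130.134825	10,11
130C	130.141145	10,11
131N	131.138180	10,11
131C	131.144500	11
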