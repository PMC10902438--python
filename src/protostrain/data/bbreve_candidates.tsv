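ncbi_code	strain	ani	avg_ppos	published_score
GCA_000568955.1	PRL2012	98.2	96.43	9469.6
GCA_000568895.1	2L	98.2	96.43	9468.8
GCA_000568875.1	31L	98.0	96.18	9422.1
GCA_002075865.1	1900B	98.2	95.62	9389.6
local	676B	98.0	95.65	9375.8
GCA_000569055.1	689b	98.0	95.64	9372.5
local	158B	98.1	95.51	9368.8
GCA_002076075.1	1889B	98.1	95.51	9367.9
GCA_002076055.1	1891B	97.7	95.31	9308.7
GCA_016648985.1	M1D	97.6	95.28	9300.5
GCA_016648955.1	PRL2020	97.7	95.23	9299.8
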