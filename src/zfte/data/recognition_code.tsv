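position	residue	A	C	G	T
-1	R	0.050000	0.050000	0.850000	0.050000
-1	Q	0.850000	0.050000	0.050000	0.050000
-1	E	0.050000	0.850000	0.050000	0.050000
-1	T	0.050000	0.050000	0.050000	0.850000
-1	N	0.850000	0.050000	0.050000	0.050000
-1	K	0.050000	0.050000	0.850000	0.050000
-1	S	0.050000	0.050000	0.050000	0.850000
-1	V	0.050000	0.050000	0.050000	0.850000
-1	D	0.050000	0.850000	0.050000	0.050000
2	D	0.150000	0.550000	0.150000	0.150000
2	E	0.150000	0.550000	0.150000	0.150000
2	S	0.550000	0.150000	0.150000	0.150000
2	T	0.550000	0.150000	0.150000	0.150000
2	R	0.150000	0.150000	0.550000	0.150000
2	N	0.150000	0.150000	0.150000	0.550000
2	K	0.150000	0.150000	0.550000	0.150000
2	Q	0.550000	0.150000	0.150000	0.150000
3	H	0.050000	0.050000	0.850000	0.050000
3	N	0.850000	0.050000	0.050000	0.050000
3	D	0.050000	0.850000	0.050000	0.050000
3	A	0.050000	0.050000	0.050000	0.850000
3	S	0.050000	0.050000	0.050000	0.850000
3	T	0.050000	0.050000	0.050000	0.850000
3	V	0.050000	0.050000	0.050000	0.850000
3	E	0.050000	0.850000	0.050000	0.050000
3	K	0.050000	0.050000	0.850000	0.050000
6	R	0.050000	0.050000	0.850000	0.050000
6	Q	0.850000	0.050000	0.050000	0.050000
6	E	0.050000	0.850000	0.050000	0.050000
6	T	0.050000	0.050000	0.050000	0.850000
6	K	0.050000	0.050000	0.850000	0.050000
6	S	0.050000	0.050000	0.050000	0.850000
6	D	0.050000	0.850000	0.050000	0.050000
6	N	0.850000	0.050000	0.050000	0.050000
6	V	0.050000	0.050000	0.050000	0.850000
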