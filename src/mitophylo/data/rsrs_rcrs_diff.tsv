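# Sites at which the rCRS differs from the RSRS ancestral root, written as
# variant tokens in rCRS coordinates (the standard translation set used to
# re-express rCRS-relative profiles against the RSRS root).
73
146
152
195
247
263
750
769
825T
1018
1438
2706
2758
2885
3594
4104
4312
4769
7028
7146
7256
7521
8468
8655
8701
8860
9540
10398
10664
10688
10810
10873
10915
11719
11914
12705
13105
13276
13506
13650
14766
15326
16129
16187
16189
16223
16230
16278
16311
16519
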