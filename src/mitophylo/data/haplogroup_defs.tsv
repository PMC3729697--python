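# Haplogroup definition tree for the N1a1b/I and W clade system (rCRS-relative
# coordinates; root sentinel rCRS).  status: printed = branch motif as published;
# standard = conventional control-region signature of the clade; inferred = partly
# reconstructed from published haplotypes; placeholder = synthetic stand-in
# positions (the clade name is real, its defining sites are not).
name	parent	status	motif
N	rCRS	standard	73 263 750 1438 2706 4769 7028 8860 11719 14766 15326 16223
N1	N	standard	10238
N1a	N1	placeholder	3085
N1a1	N1a	placeholder	3122
N1a1b	N1a1	standard	199 250 16391
N1a1b1	N1a1b	printed	143 710 10790
N1a1b1a	N1a1b1	placeholder	3233
N1a1b1a1	N1a1b1a	placeholder	3270
I	N1a1b	printed	10034 16129
I1	I	placeholder	3344
I1a	I1	printed	3447 8616T 16172
I1a1	I1a	printed	203
I1a1a	I1a1	placeholder	3455
I1a1b	I1a1	placeholder	3492
I1a1c	I1a1	placeholder	3529
I1a1d	I1a1	placeholder	3566
I1b	I1	placeholder	3603
I1c	I1	inferred	3640 16264 16270
I1c1	I1c	inferred	3677 16319 16362
I1c1a	I1c1	placeholder	3714
I5	I	placeholder	3751
I5a	I5	placeholder	3788
I5a1	I5a	placeholder	3825
I5a2	I5a	placeholder	3862
I5a2a	I5a2	placeholder	3899
I5a3	I5a	placeholder	3936
I5a4	I5a	placeholder	3973
I5b	I5	placeholder	4010
I6	I	placeholder	4047
I6a	I6	placeholder	4084
I6b	I6	placeholder	4121
I7	I	placeholder	4158
I2'3	I	printed	152 207
I2	I2'3	placeholder	4232
I2a	I2	placeholder	4269
I2a1	I2a	placeholder	4306
I2b	I2	placeholder	4343
I2c	I2	placeholder	4380
I2d	I2	placeholder	4417
I2e	I2	placeholder	4454
I3	I2'3	placeholder	4491
I3a	I3	placeholder	4528
I3a1	I3a	placeholder	4565
I3b	I3	placeholder	4602
I3c	I3	placeholder	4639
I4	I	placeholder	4676
I4a	I4	placeholder	4713
I4a1	I4a	placeholder	4750
I4b	I4	placeholder	4787
N2	N	standard	189 194 195
W	N2	printed	195@ 204 207 1243 3505 5460 8251 8994 11947 15884C 16292
W1	W	placeholder	4898
W1a	W1	placeholder	4935
W1b	W1	placeholder	4972
W1b1	W1b	placeholder	5009
W1c	W1	inferred	119 5046
W1c1	W1c	placeholder	5083
W1e	W1	placeholder	5120
W1f	W1	placeholder	5157
W1g	W1	placeholder	5194
W3	W	printed	1406
W3a	W3	placeholder	5268
W3a1	W3a	placeholder	5305
W3a1a	W3a1	placeholder	5342
W3a1a1	W3a1a	placeholder	5379
W3a1a2	W3a1a	placeholder	5416
W3a1b	W3a1	placeholder	5453
W3a1c	W3a1	placeholder	5490
W3a2	W3a	placeholder	5527
W3b	W3	placeholder	5564
W3b1	W3b	placeholder	5601
W4	W	placeholder	5638
W4a	W4	placeholder	5675
W5	W	placeholder	5712
W5a	W5	inferred	5749 16362
W5a1	W5a	placeholder	5786
W5a1a	W5a1	placeholder	5823
W5a1a1	W5a1a	placeholder	5860
W5a1a1a	W5a1a1	placeholder	5897
W5a2	W5a	placeholder	5934
W5b	W5	placeholder	5971
W6	W	printed	4093 8614 16325
W6a	W6	inferred	16192 16150
W6b	W6	inferred	16192 16157
W6c	W6	placeholder	6119
W7	W	printed	185
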