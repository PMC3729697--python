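# Recurrent-mutation-prone control-region sites and their down-weighting for
# tree construction tie-breaks (weight < 1 = less reliable as shared-derived
# evidence) doubling as relative rate multipliers for the mutation simulator.
position	weight	rate_multiplier
146	0.5	6
150	0.5	6
152	0.3	10
185	0.5	6
189	0.5	6
195	0.3	10
204	0.5	5
207	0.5	5
16093	0.5	6
16129	0.5	8
16182	0.3	10
16183	0.3	10
16189	0.3	10
16192	0.5	6
16311	0.5	8
16362	0.5	6
16519	0.2	14
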