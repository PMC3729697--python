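# Published control-region haplotypes of ancient European/Central Asian
# specimens assigned to haplogroups I and W (rCRS-relative tokens).
# covered: sequenced ranges; "HVS-I" = 16024-16365, "HVS-II" = 34-287.
country	site	date_bc	period	published_haplogroup	haplotype	covered
Spain	Paternanbidea	6090-5960	Neolithic	I	16129 16233	HVS-I;HVS-II
Spain	Cami de Can Grau	3500-3000	Neolithic	I1c1	16223 16264 16270 16311 16319 16362	HVS-I
Germany	Kromsdorf	2600-2500	Late Neolithic (Bell Beaker)	I1a1	16129 16172 16223 16311 16391 73 199 203 204 250 263	15995-16429;34-287
Germany	Eulau	2563-2465	Late Neolithic (Corded Ware)	I	16129 16223 16391	15997-16409
Germany	Esperstedt	2050-1800	Late Neolithic (Unetice)	I	16129 16223 16278 16311 16391	15997-16409
Germany	Esperstedt	2050-1800	Late Neolithic (Unetice)	I	16086 16129 16223 16391	15997-16409
Kazakhstan	Vodokhranilische	1400-1000	Bronze Age (Kurgan)	I	16129 16223 16294	HVS-I
Germany	Derenburg Meerenstieg II	5000	Early Neolithic (LBK)	W	16093 16223 16292	15997-16409
Germany	Derenburg Meerenstieg II	5000	Early Neolithic (LBK)	W	16093 16223 16292	15997-16409
Spain	Cami de Can Grau	3500-3000	Neolithic	W	16223 16292 16295 16304	HVS-I
Germany	Kromsdorf	2600-2500	Late Neolithic (Bell Beaker)	W5a?	16223 16292 16362 73 189 194 195 204 207 263	15995-16429;34-287
Germany	Esperstedt	2700-2000	Late Neolithic (Corded Ware)	W6	16192 16223 16292 16325	15997-16409
Germany	Esperstedt	2050-1800	Late Neolithic (Unetice)	W	16147G 16223 16292	15997-16409
Kazakhstan	Zevakinskiy	800-700	Bronze/Iron Age	W	16223 16292	HVS-I
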