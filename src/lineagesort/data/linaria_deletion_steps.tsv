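taxon	its_A	its_B	its_C	agt1_A	agt1_B	agt1_C	cp_A	cp_B	cp_C	published_average
L. glauca ssp. olcadium	-4	-2	-4	-3	-2	-2	-2	-2	-2	-2.56
L. orbensis	-4	0	-4	1	1	1	-2	-2	-2	-1.22
L. amethystea ssp. amethystea	-3	-1	-3	-1	0	1	-1	-1	-1	-1.11
L. cuartanensis	1	-1	-1	-1	-1	-1	-1	-2	-2	-1.00
L. tursica	2	2	0	-2	-2	-1	-2	-2	0	-0.56
L. oblongifolia ssp. oblongifolia	0	0	0	-2	-1	-1	0	0	0	-0.44
L. alpina	0	2	0	-1	-1	1	0	-2	-2	-0.33
L. filicaulis	0	0	0	-1	-1	-1	0	0	0	-0.33
L. saturejoides ssp. saturejoides	0	0	0	-2	0	0	0	0	0	-0.22
L. propinqua	-2	1	-2	-1	1	1	0	0	0	-0.22
L. supina ssp. supina	0	2	-2	-1	1	1	0	0	0	0.11
L. bubanii	0	2	-2	1	-1	1	0	-1	1	0.11
L. bipunctata ssp. bipunctata	-2	2	0	-1	0	0	0	2	0	0.11
L. saxatlis	-2	3	-2	1	0	1	0	0	0	0.11
L. badalii	-1	3	-1	-1	-1	-1	1	1	1	0.11
L. almijarensis	1	3	1	-1	-1	-1	1	0	0	0.33
L. mumbyana	1	3	1	-1	0	-1	1	0	0	0.44
L. aeruginea	1	1	1	0	1	1	0	-1	0	0.44
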