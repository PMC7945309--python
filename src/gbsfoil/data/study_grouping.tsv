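population	taxon	n_individuals	taxon_representative
BA231	baldaccii	5	0
BA232	baldaccii	5	1
CA217	capillacea	5	1
CA233	capillacea_albanian	5	1
CA48	capillacea	5	0
CA53	capillacea	0	0
CA64	capillacea	5	0
DI230	dirphya	5	1
DO222	doerfleri	2	1
GA223	garckeana	5	0
GA224	garckeana	4	0
GA226	garckeana	5	0
GA227	garckeana	5	0
GA228	garckeana	5	1
LN38	langii	5	0
LN39	langii	5	0
LN54	langii	5	0
LN56	langii	5	0
LN57	langii	5	0
LN58	langii	5	0
LN59	langii	4	0
LN60	langii	4	0
LN61	langii	5	0
LN71	langii	5	0
LN72	langii	3	0
LN74	langii	5	0
LN76	langii	4	0
LN77	langii	2	1
LN79	langii	5	0
LN80	langii	5	0
LL40	laricifolia_laricifolia	5	0
LL41	laricifolia_laricifolia	5	0
LL42	laricifolia_laricifolia	5	0
LL47	laricifolia_laricifolia	5	0
LL49	laricifolia_laricifolia	5	1
LL55	laricifolia_laricifolia	5	0
LL62	laricifolia_laricifolia	4	0
LL65	laricifolia_laricifolia	5	0
LL66	laricifolia_laricifolia	4	0
LL67	laricifolia_laricifolia	5	0
LL68	laricifolia_laricifolia	5	0
LL85	laricifolia_laricifolia	4	0
LL86	laricifolia_laricifolia	4	0
LL88	laricifolia_laricifolia	4	0
LL89	laricifolia_laricifolia	5	0
LL92	laricifolia_laricifolia	4	0
LL95	laricifolia_laricifolia	2	0
LL96	laricifolia_laricifolia	5	0
LL98	laricifolia_laricifolia	5	0
LL99	laricifolia_laricifolia	5	0
LL218	laricifolia_laricifolia	5	0
LL219	laricifolia_laricifolia	3	0
LL220	laricifolia_laricifolia	5	0
LL273	laricifolia_laricifolia	5	0
LO50	laricifolia_ophiolitica	5	1
LO51	laricifolia_ophiolitica	5	0
LO52	laricifolia_ophiolitica	5	0
PA	parnonia	4	0
PA229	parnonia	1	1
LA237	rupestris	5	1
SE152	sedoides	1	1
SE46	sedoides	1	0
WE	wettsteinii	4	1
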