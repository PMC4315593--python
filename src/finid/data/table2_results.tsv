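num	type	loc	bold	blast_top_hit	coverage	identity	unq	id
1	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
2	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
3	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
4	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
5	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
6	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
7	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
8	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
9	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
10	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
11	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
12	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
13	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
14	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
15	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
16	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
17	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
18	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
19	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
20	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
21	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
22	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
23	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
24	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
25	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
26	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
27	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
28	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
29	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
30	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
31	P	HK	Carcharhinus spp.	Carcharhinus falciformis	98	100	No	Requiem/whaler
32	P	HK	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
33	P	HK	Carcharhinus sorrah	Carcharhinus sorrah	100	100	Yes	Spottail
34	P	HK	Carcharhinus spp.	Carcharhinus obscurus	100	100	No	Requiem/whaler
35	P	HK	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
36	P	HK	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
37	P	HK	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
38	P	HK	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
39	P	HK	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
40	P	HK	Prionace glauca	Prionace glauca	100	100	Yes	Blue
41	P	HK	Prionace glauca	Prionace glauca	100	100	Yes	Blue
42	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
43	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
44	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
45	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
46	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
47	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
48	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
49	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
50	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
51	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
52	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
53	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
54	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
55	S	USA	Prionace glauca	Prionace glauca	100	100	Yes	Blue
56	S	USA	Prionace glauca	Prionace glauca	100	99	Yes	Blue
57	S	USA	Carcharhinus leucas	Carcharhinus leucas	100	100	Yes	Bull
58	S	USA	Squalus spp.	Squalus acanthias	100	100	No	Dogfish
59	S	USA	Mustelus schmitti	Mustelus schmitti	100	100	Yes	Narrownose smoothound
60	S	USA	Carcharhinus spp.	Carcharhinus tilstoni	100	100	No	Requiem/whaler
61	S	USA	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
62	S	USA	Carcharhinus spp.	Carcharhinus falciformis	100	100	No	Requiem/whaler
63	S	USA	Carcharhinus spp.	Carcharhinus amboinensis	100	99	No	Requiem/whaler
64	S	USA	Carcharhinus spp.	Carcharhinus amboinensis	100	99	No	Requiem/whaler
65	S	USA	Sphyrna lewini	Sphyrna lewini	100	100	Yes	Scalloped hammerhead
66	S	USA	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
67	S	USA	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
68	S	USA	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
69	S	USA	Galeorhinus galeus	Galeorhinus galeus	100	100	Yes	School
70	S	USA	Isurus oxyrinchus	Isurus oxyrinchus	100	100	Yes	Shortfin Mako
71	S	USA	Sphyrna zygaena	Sphyrna zygaena	100	100	Yes	Smooth hammerhead
72	S	USA	Sphyrna zygaena	Sphyrna zygaena	99	100	Yes	Smooth hammerhead
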