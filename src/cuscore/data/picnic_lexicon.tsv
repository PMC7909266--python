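cu_id	sub_id	category	variant	control_count	referents
1		unambiguous-entity	kite	31
2		unambiguous-entity	house	31
2		unambiguous-entity	home	31
2		unambiguous-entity	rental	31
2		unambiguous-entity	cottage	31
2		unambiguous-entity	cabin	31
3		unambiguous-entity	wine	31
3		unambiguous-entity	drink	31
3		unambiguous-entity	liquid	31
3		unambiguous-entity	drinks	31
3		unambiguous-entity	beverage	31
3		unambiguous-entity	soda	31
3		unambiguous-entity	juice	31
3		unambiguous-entity	champagne	31
4		unambiguous-entity	dog	30
4		unambiguous-entity	puppy	30
5		unambiguous-entity	beach	29
5		unambiguous-entity	sand	29
6		unambiguous-entity	sailboat	28
6		unambiguous-entity	boat	28
7		unambiguous-entity	picnic	28
7		unambiguous-entity	picnicking	28
8		unambiguous-entity	woman	27
8		unambiguous-entity	mother	27
8		unambiguous-entity	mom	27
8		unambiguous-entity	wife	27
8		unambiguous-entity	lady	27
9		unambiguous-entity	sandcastle	26
9		unambiguous-entity	pile	26
9		unambiguous-entity	castle	26
10		unambiguous-entity	water	26
10		unambiguous-entity	lake	26
10		unambiguous-entity	ocean	26
10		unambiguous-entity	river	26
10		unambiguous-entity	sea	26
11		unambiguous-entity	boy	26
11		unambiguous-entity	son	26
12		unambiguous-entity	girl	24
12		unambiguous-entity	daughter	24
13		unambiguous-entity	pier	21
13		unambiguous-entity	dock	21
14		unambiguous-entity	book	18
15		unambiguous-entity	tree	18
16		unambiguous-entity	car	16
17		unambiguous-entity	driveway	16
17		unambiguous-entity	path	16
17		unambiguous-entity	road	16
17		unambiguous-entity	street	16
18		unambiguous-entity	garage	15
18		unambiguous-entity	parked	15
19		unambiguous-entity	shoes	15
19		unambiguous-entity	sandals	15
19		unambiguous-entity	sneakers	15
20		unambiguous-entity	fish	13
21		unambiguous-entity	couple	13
21		unambiguous-entity	two	13
21		unambiguous-entity	parents	13
22		unambiguous-entity	radio	13
22		unambiguous-entity	boombox	13
23		unambiguous-entity	flag	11
23		unambiguous-entity	flagpole	11
24		unambiguous-entity	glass	11
24		unambiguous-entity	cup	11
24		unambiguous-entity	glasses	11
25		unambiguous-entity	blanket	10
25		unambiguous-entity	carpet	10
26		unambiguous-entity	shovel	8
27		unambiguous-entity	pail	7
27		unambiguous-entity	bucket	7
28		unambiguous-entity	sky	7
28		unambiguous-entity	clouds	7
29		unambiguous-entity	fisherman	6
30		unambiguous-entity	basket	4
31		unambiguous-entity	man's glasses	3
32		unambiguous-entity	bottle	3
32		unambiguous-entity	thermos	3
33		unambiguous-action	fishing	31
33		unambiguous-action	caught	31
33		unambiguous-action	catching	31
34		unambiguous-action	flying	31
34		unambiguous-action	pulling	31
35		unambiguous-action	building	31
35		unambiguous-action	making	31
35		unambiguous-action	playing	31
35		unambiguous-action	built a sandcastle	31
36		unambiguous-action	reading	26
37		unambiguous-action	pouring	21
38		unambiguous-action	enjoying	18
38		unambiguous-action	relaxing	18
38		unambiguous-action	happy	18
38		unambiguous-action	having a good time	18
38		unambiguous-action	relaxed	18
38		unambiguous-action	fun	18
39		unambiguous-action	chasing	17
39		unambiguous-action	following	17
39		unambiguous-action	chased	17
40		unambiguous-action	sailing	8
40		unambiguous-action	cruising	8
41		unambiguous-property	beautiful	17
41		unambiguous-property	idyllic	17
41		unambiguous-property	nice	17
41		unambiguous-property	lovely	17
41		unambiguous-property	pleasant	17
41		unambiguous-property	calm	17
42		unambiguous-property	big	10
42		unambiguous-property	large	10
43		ambiguous-entity	man	31
43		ambiguous-entity	father	31
43		ambiguous-entity	dad	31
43		ambiguous-entity	gentleman	31
43		ambiguous-entity	grandpa	31
43		ambiguous-entity	husband	31
43		ambiguous-entity	hubby	31
43		ambiguous-entity	pops	31
43	43a	ambiguous-entity		18	42
43	43b	ambiguous-entity		15	29
44		ambiguous-entity	grass	31	no-pattern
44		ambiguous-entity	yard	31	no-pattern
44		ambiguous-entity	shrubbery	31	no-pattern
44		ambiguous-entity	park	31	no-pattern
44		ambiguous-entity	enclave	31	no-pattern
44		ambiguous-entity	grassy	31	no-pattern
44		ambiguous-entity	place	31	no-pattern
44		ambiguous-entity	bushes	31	no-pattern
44		ambiguous-entity	environment	31	no-pattern
44		ambiguous-entity	foliage	31	no-pattern
44		ambiguous-entity	gable	31	no-pattern
44		ambiguous-entity	hill	31	no-pattern
44		ambiguous-entity	mountains	31	no-pattern
44		ambiguous-entity	scenery	31	no-pattern
44		ambiguous-entity	spot	31	no-pattern
44		ambiguous-entity	trees	31	no-pattern
44		ambiguous-entity	forest	31	no-pattern
45		ambiguous-entity	someone	30
45		ambiguous-entity	guy	30
45		ambiguous-entity	fellow	30
45		ambiguous-entity	somebody	30
45		ambiguous-entity	person	30
45		ambiguous-entity	jabroni	30
45		ambiguous-entity	adult	30
45	45a	ambiguous-entity			11
45	45b	ambiguous-entity			12
45	45c	ambiguous-entity			42
45	45d	ambiguous-entity			29
46		ambiguous-entity	family	24
46		ambiguous-entity	people	24
46		ambiguous-entity	everyone	24
46		ambiguous-entity	families	24
46		ambiguous-entity	occupants	24
46	46a	ambiguous-entity			11,12,8,42
46	46b	ambiguous-entity			11,12,8,42,29
46	46c	ambiguous-entity			no-pattern
47		ambiguous-entity	inlet	12
47		ambiguous-entity	lakeside	12
47		ambiguous-entity	seashore	12
47		ambiguous-entity	seaside	12
47		ambiguous-entity	bay	12
47		ambiguous-entity	oceanside	12
47		ambiguous-entity	shore	12
47		ambiguous-entity	wharf	12
47	47a	ambiguous-entity			58
47	47b	ambiguous-entity			12
47	47c	ambiguous-entity			29
48		ambiguous-entity	kid	8
48		ambiguous-entity	kids	8
48		ambiguous-entity	children	8
48	48a	ambiguous-entity			11
48	48b	ambiguous-entity			12
49		ambiguous-entity	shorts	5
49	49a	ambiguous-entity			11
49	49b	ambiguous-entity			8+42
49	49c	ambiguous-entity			42
50		ambiguous-entity	t-shirt	3
50	50a	ambiguous-entity			11
50	50b	ambiguous-entity			8
51		ambiguous-action	running	12
51	51a	ambiguous-action			11
51	51b	ambiguous-action			4
51	51c	ambiguous-action			11+4
52		ambiguous-action	sitting	6
52	52a	ambiguous-action			8
52	52b	ambiguous-action			42
52	52c	ambiguous-action			8+42
53		ambiguous-action	wearing	5
53	53a	ambiguous-action			11
53	53b	ambiguous-action			8+42
53	53c	ambiguous-action			42
53	53d	ambiguous-action			29
54		ambiguous-action	bloom	4	15
54		ambiguous-action	blossomed	4	15
54		ambiguous-action	blooming	4	15
55		ambiguous-property	little	27
55		ambiguous-property	young	27
55		ambiguous-property	younger	27
55	55a	ambiguous-property			11
55	55b	ambiguous-property			12
55	55c	ambiguous-property			4
55	55d	ambiguous-property			2
55	55e	ambiguous-property			43
56		inferred	summer	20
56		inferred	sun	20
56		inferred	sunny	20
56		inferred	summertime	20
56		inferred	weather	20
56		inferred	season	20
56		inferred	spring	20
56		inferred	warm	20
57		inferred	music	16
57		inferred	listening to	16
58		inferred	day	16
58		inferred	afternoon	16
58		inferred	vacation	16
58		inferred	retreat	16
59		inferred	scene	9
59		inferred	picture	9
60		inferred	activities	9
60		inferred	recreational	9
60		inferred	sport	9
61		inferred	outside	8
62		inferred	breeze	4
62		inferred	windy	4
63		inferred	sandwich	4
63		inferred	food	4
64		spatial-relation	across	31
64		spatial-relation	around	31
64		spatial-relation	background	31
64		spatial-relation	behind	31
64		spatial-relation	beside	31
64		spatial-relation	close	31
64		spatial-relation	distance	31
64		spatial-relation	distant	31
64		spatial-relation	far	31
64		spatial-relation	foreground	31
64		spatial-relation	front	31
64		spatial-relation	left	31
64		spatial-relation	nearby	31
64		spatial-relation	next to	31
64		spatial-relation	right	31
64		spatial-relation	side	31
64	64a	spatial-relation			2
64	64b	spatial-relation			6
64	64c	spatial-relation			11
64	64d	spatial-relation			15
64	64e	spatial-relation			23
64	64f	spatial-relation			4
64	64g	spatial-relation			21
64	64h	spatial-relation			29
64	64i	spatial-relation			43
64	64j	spatial-relation			16
64	64k	spatial-relation			22
64	64l	spatial-relation			17
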