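item_id,word,valence
1,shrewd,desirable
2,frivolous,undesirable
3,humorless,undesirable
4,persistent,desirable
5,moody,undesirable
6,serious,desirable
7,unimaginative,undesirable
8,warm,desirable
9,modest,desirable
10,wasteful,undesirable
11,boring,undesirable
12,wavering,undesirable
13,insignificant,undesirable
14,good natured,desirable
15,humorous,desirable
16,important,desirable
17,calm,desirable
18,squeamish,undesirable
19,irritable,undesirable
20,happy,desirable
21,dominating,undesirable
22,skillful,desirable
23,unsociable,undesirable
24,sentimental,undesirable
25,pessimistic,undesirable
26,cautious,desirable
27,imaginative,desirable
28,foolish,undesirable
29,vain,undesirable
30,sincere,desirable
31,unreliable,undesirable
32,practical,desirable
33,superficial,undesirable
34,critical,undesirable
35,reliable,desirable
36,submissive,desirable
37,dishonest,undesirable
38,clumsy,undesirable
39,unintelligent,undesirable
40,impulsive,undesirable
41,popular,desirable
42,honest,desirable
43,industrious,desirable
44,determined,desirable
45,sociable,desirable
46,unhappy,undesirable
47,intelligent,desirable
48,irresponsible,undesirable
49,discriminating,desirable
50,helpful,desirable
51,tolerant,desirable
52,unpopular,undesirable
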