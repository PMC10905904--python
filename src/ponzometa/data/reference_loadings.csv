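item_id,word,pc1,pc2,pc3
1,shrewd,0.266,-0.054,-0.121
2,frivolous,0.299,0.149,0.007
3,humorless,0.256,-0.107,-0.124
4,persistent,0.289,0.312,0.111
5,moody,0.036,0.197,0.117
6,serious,0.076,0.217,0.198
7,unimaginative,0.182,-0.139,-0.211
8,warm,0.215,0.056,0.067
9,modest,-0.084,0.188,0.066
10,wasteful,0.035,0.326,0.103
11,boring,0.341,-0.021,-0.021
12,wavering,0.156,-0.155,-0.202
13,insignificant,0.315,-0.074,0.087
14,good natured,0.306,-0.240,0.116
15,humorous,0.273,-0.079,-0.072
16,important,0.257,-0.003,0.019
17,calm,0.041,0.104,-0.246
18,squeamish,0.134,-0.039,-0.019
19,irritable,0.017,0.081,-0.176
20,happy,0.259,-0.243,0.132
21,dominating,-0.115,0.215,-0.126
22,skillful,0.156,-0.006,-0.192
23,unsociable,0.389,-0.178,0.142
24,sentimental,0.138,0.137,-0.259
25,pessimistic,0.244,-0.116,-0.162
26,cautious,-0.139,0.187,-0.176
27,imaginative,0.174,-0.154,-0.201
28,foolish,0.171,0.098,-0.082
29,vain,-0.001,0.159,-0.077
30,sincere,0.203,0.073,-0.026
31,unreliable,0.398,0.098,-0.042
32,practical,0.215,0.129,-0.002
33,superficial,0.217,0.146,-0.031
34,critical,0.036,0.244,-0.052
35,reliable,0.307,0.081,0.002
36,submissive,-0.125,-0.004,-0.069
37,dishonest,0.143,0.179,0.148
38,clumsy,0.203,0.066,-0.200
39,unintelligent,0.173,0.081,-0.109
40,impulsive,-0.145,0.267,-0.018
41,popular,0.167,-0.069,-0.016
42,honest,0.104,0.258,-0.025
43,industrious,0.211,0.346,0.006
44,determined,0.305,-0.047,0.069
45,sociable,0.406,-0.117,0.221
46,unhappy,0.375,-0.084,0.135
47,intelligent,0.118,0.024,-0.114
48,irresponsible,0.280,0.290,0.102
49,discriminating,0.263,0.041,-0.124
50,helpful,0.172,0.101,0.122
51,tolerant,-0.001,0.062,-0.215
52,unpopular,0.346,-0.039,-0.100
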