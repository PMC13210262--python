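age_months,L,M,S
24,-0.15,12.4,0.105
25,-0.15231,12.5145,0.1051
26,-0.15505,12.6327,0.10524
27,-0.1582,12.7547,0.10541
28,-0.16173,12.8803,0.10561
29,-0.1656,13.0093,0.10584
30,-0.16979,13.1417,0.1061
31,-0.17427,13.2774,0.10638
32,-0.17901,13.4161,0.10667
33,-0.18398,13.5579,0.10699
34,-0.18916,13.7025,0.10731
35,-0.19451,13.8499,0.10765
36,-0.2,14.0,0.108
37,-0.20607,14.1551,0.10838
38,-0.21307,14.3172,0.10881
39,-0.22083,14.4851,0.1093
40,-0.22922,14.658,0.10983
41,-0.23807,14.8348,0.11039
42,-0.24722,15.0145,0.111
43,-0.25653,15.1963,0.11162
44,-0.26584,15.379,0.11228
45,-0.275,15.5617,0.11295
46,-0.28385,15.7434,0.11363
47,-0.29223,15.9232,0.11431
48,-0.3,16.1,0.115
49,-0.30732,16.2744,0.11571
50,-0.31449,16.4478,0.11646
51,-0.3215,16.6205,0.11725
52,-0.32838,16.7929,0.11807
53,-0.33513,16.9653,0.11892
54,-0.34178,17.1381,0.11978
55,-0.34832,17.3115,0.12065
56,-0.35478,17.4859,0.12154
57,-0.36117,17.6616,0.12242
58,-0.36749,17.839,0.12329
59,-0.37376,18.0183,0.12416
60,-0.38,18.2,0.125
61,-0.38623,18.3837,0.12581
62,-0.39248,18.569,0.12659
63,-0.3987,18.7558,0.12734
64,-0.40489,18.9441,0.12809
65,-0.41101,19.1338,0.12883
66,-0.41704,19.325,0.12958
67,-0.42296,19.5175,0.13036
68,-0.42874,19.7114,0.13117
69,-0.43436,19.9066,0.13203
70,-0.43979,20.1032,0.13295
71,-0.44501,20.301,0.13393
72,-0.45,20.5,0.135
73,-0.45475,20.6999,0.1362
74,-0.4593,20.9003,0.13756
75,-0.46367,21.1017,0.13906
76,-0.4679,21.3042,0.14068
77,-0.47201,21.5081,0.14239
78,-0.47604,21.7138,0.14417
79,-0.48001,21.9215,0.14599
80,-0.48395,22.1315,0.14784
81,-0.48789,22.3441,0.14969
82,-0.49186,22.5595,0.15151
83,-0.49589,22.778,0.15329
84,-0.5,23.0,0.155
85,-0.50425,23.2257,0.15667
86,-0.50862,23.4552,0.15833
87,-0.51309,23.6881,0.16
88,-0.51759,23.9243,0.16167
89,-0.5221,24.1634,0.16333
90,-0.52656,24.4053,0.165
91,-0.53094,24.6497,0.16667
92,-0.53519,24.8963,0.16833
93,-0.53926,25.1449,0.17
94,-0.54311,25.3952,0.17167
95,-0.54671,25.647,0.17333
96,-0.55,25.9,0.175
97,-0.55306,26.155,0.17668
98,-0.55601,26.4129,0.1784
99,-0.55884,26.6733,0.18013
100,-0.56156,26.9362,0.18188
101,-0.56417,27.2012,0.18362
102,-0.56669,27.4682,0.18536
103,-0.56911,27.737,0.18707
104,-0.57144,28.0073,0.18876
105,-0.5737,28.279,0.1904
106,-0.57587,28.5518,0.192
107,-0.57797,28.8255,0.19353
108,-0.58,29.1,0.195
109,-0.58207,29.3744,0.19643
110,-0.58426,29.6484,0.19787
111,-0.5865,29.9226,0.19931
112,-0.58874,30.1976,0.20072
113,-0.59093,30.4741,0.20211
114,-0.593,30.7527,0.20345
115,-0.59491,31.0338,0.20474
116,-0.59659,31.3182,0.20597
117,-0.598,31.6064,0.20712
118,-0.59907,31.899,0.20818
119,-0.59976,32.1967,0.20915
120,-0.6,32.5,0.21
121,-0.6,32.8091,0.21078
122,-0.6,33.1237,0.21153
123,-0.6,33.4434,0.21224
124,-0.6,33.7679,0.21292
125,-0.6,34.0969,0.21356
126,-0.6,34.43,0.21417
127,-0.6,34.7671,0.21474
128,-0.6,35.1078,0.21527
129,-0.6,35.4517,0.21576
130,-0.6,35.7986,0.21622
131,-0.6,36.1481,0.21663
132,-0.6,36.5,0.217
133,-0.6,36.8555,0.21735
134,-0.6,37.216,0.21771
135,-0.6,37.581,0.21806
136,-0.6,37.95,0.2184
137,-0.6,38.3228,0.21872
138,-0.6,38.6988,0.21902
139,-0.6,39.0776,0.2193
140,-0.6,39.4589,0.21953
141,-0.6,39.8422,0.21973
142,-0.6,40.2271,0.21988
143,-0.6,40.6132,0.21997
144,-0.6,41.0,0.22
145,-0.59976,41.3895,0.21993
146,-0.59907,41.7832,0.21975
147,-0.598,42.1806,0.21945
148,-0.59659,42.5808,0.21907
149,-0.59491,42.9832,0.21863
150,-0.593,43.387,0.21813
151,-0.59093,43.7915,0.21759
152,-0.58874,44.196,0.21704
153,-0.5865,44.5998,0.21648
154,-0.58426,45.0023,0.21595
155,-0.58207,45.4026,0.21545
156,-0.58,45.8,0.215
157,-0.57792,46.1975,0.21459
158,-0.57569,46.5978,0.21421
159,-0.57334,46.9997,0.21383
160,-0.57089,47.402,0.21346
161,-0.56835,47.8036,0.21309
162,-0.56575,48.2035,0.21271
163,-0.56311,48.6003,0.21232
164,-0.56044,48.993,0.21191
165,-0.55778,49.3805,0.21148
166,-0.55514,49.7616,0.21103
167,-0.55254,50.1351,0.21053
168,-0.55,50.5,0.21
169,-0.54746,50.8587,0.20938
170,-0.54486,51.2142,0.20864
171,-0.54222,51.5661,0.20781
172,-0.53956,51.9139,0.20691
173,-0.53689,52.2573,0.20597
174,-0.53425,52.5958,0.205
175,-0.53165,52.9289,0.20403
176,-0.52911,53.2564,0.20309
177,-0.52666,53.5776,0.20219
178,-0.52431,53.8922,0.20136
179,-0.52208,54.1998,0.20062
180,-0.52,54.5,0.2
181,-0.51808,54.7945,0.19947
182,-0.5163,55.0851,0.19897
183,-0.51462,55.3714,0.19852
184,-0.51304,55.6532,0.19809
185,-0.5115,55.93,0.19768
186,-0.51,56.2016,0.19729
187,-0.5085,56.4675,0.19691
188,-0.50696,56.7274,0.19654
189,-0.50538,56.981,0.19617
190,-0.5037,57.2278,0.19579
191,-0.50192,57.4676,0.19541
192,-0.5,57.7,0.195
193,-0.49789,57.9264,0.19458
194,-0.49558,58.1486,0.19417
195,-0.49312,58.3662,0.19376
196,-0.49053,58.5792,0.19335
197,-0.48787,58.7875,0.19294
198,-0.48515,58.9908,0.19253
199,-0.48243,59.1891,0.19211
200,-0.47973,59.3822,0.1917
201,-0.47711,59.57,0.19128
202,-0.47458,59.7523,0.19086
203,-0.4722,59.929,0.19043
204,-0.47,60.1,0.19
205,-0.46792,60.2663,0.18956
206,-0.46589,60.4289,0.18912
207,-0.4639,60.5877,0.18868
208,-0.46197,60.7425,0.18823
209,-0.46008,60.8932,0.18778
210,-0.45826,61.0395,0.18732
211,-0.45648,61.1813,0.18687
212,-0.45477,61.3185,0.1864
213,-0.45312,61.4507,0.18594
214,-0.45153,61.578,0.18547
215,-0.45,61.7,0.185
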