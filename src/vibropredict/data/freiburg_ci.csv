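score,half_width
0.0,0.0
5.0,9.552
10.0,13.148
15.0,15.649
20.0,17.531
25.0,18.978
30.0,20.084
35.0,20.904
40.0,21.471
45.0,21.804
50.0,21.913
55.0,21.804
60.0,21.471
65.0,20.904
70.0,20.084
75.0,18.978
80.0,17.531
85.0,15.649
90.0,13.148
95.0,9.552
100.0,0.0
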