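compound_index,name,p_model1,p_model2,printed_call,printed_confidence,printed_logrba
6,,0.984,1.000,+,0.984,-1.004
7,,0.984,0.800,+,0.784,-0.831
8,,0.788,0.600,+,0.388,0.786
9,,0.984,1.000,+,0.984,-0.704
10,,0.984,1.000,+,0.984,-1.903
11,,0.984,1.000,+,0.984,-1.064
12,,0.984,0.943,+,0.927,-0.380
13,,0.784,0.543,+,0.327,-2.338
14,,0.784,0.743,+,0.527,-0.214
15,,0.984,0.972,+,0.962,-2.222
16,Triguaiacol,0.984,0.600,+,0.584,NA
17,Bisguaiacol E,0.834,0.600,+,0.434,-1.117
18,BGF-Catechol,0.984,0.943,+,0.927,-1.862
19,Bisguaiacol-F (BGF),0.984,0.600,+,0.584,-1.760
20,MDA-13,0.003,0.004,-,0.993,
21,Me-DFDA,0.003,0.404,-,0.592,
22,DFDA,0.203,0.404,-,0.392,
23,MDA-30,0.123,0.401,-,0.475,
24,MDA-13,0.317,0.444,-,0.238,
25,p-Cymene,0.453,0.333,-,0.213,
26,,0.216,0.400,-,0.384,
27,,0.616,0.300,-,0.084,
28,,0.316,0.350,-,0.334,
29,,0.566,0.300,-,0.134,
30,,0.566,0.300,-,0.134,
31,BHMF,0.033,0.363,-,0.604,
32,Isosorbide,0.203,0.363,-,0.434,
33,Bisguaiacol A,0.516,0.250,-,0.234,
34,BGF-Syringol,0.366,0.400,-,0.234,
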