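number,brrmsd,d3,pmf
1,2.5,11.0,9.2
2,2.5,12.0,7.6
3,2.5,13.0,7.6
3,2.5,14.0,13.9
4,2.5,15.0,20.9
5,2.5,16.0,19.1
6,3.0,10.0,3.1
7,3.0,11.0,5.3
8,3.0,12.0,7.6
9,3.0,13.0,6.8
10,3.0,14.0,10.1
11,3.0,15.0,37.5
12,3.0,16.0,22.0
13,3.0,17.0,22.8
14,3.5,10.0,0.0
15,3.5,11.0,3.9
16,3.5,12.0,6.1
17,3.5,13.0,5.6
18,3.5,14.0,7.1
19,3.5,17.0,19.1
20,3.5,18.0,26.4
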