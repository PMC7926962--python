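number,brrmsd,d3,pmf
1,1.0,11.0,32.0
2,1.0,12.0,19.1
3,1.5,11.0,7.6
4,1.5,12.0,14.2
5,1.5,13.0,8.9
6,2.5,14.0,0.0
7,3.0,13.0,31.7
8,3.0,15.0,49.8
9,3.0,16.0,28.4
10,3.0,17.0,28.5
11,3.5,16.0,15.8
12,3.5,17.0,18.5
13,3.5,18.0,21.8
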