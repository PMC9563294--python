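Phitsanulok,Phayao
19.9,9.4
20.6,16.1
26,17.3
9.4,8.6
9.8,2.9
12.6,1.8
11.6,0
0,1.4
20.9,9.7
14.8,23.4
27.3,19.8
13,3.9
0,1.1
5.4,0
3.2,0
8.7,1.8
8.7,4.3
13,22.3
25.9,21.2
8,7.6
5,0.4
3.6,1.1
5.7,0
6.2,0.7
7.6,7.2
13,15.5
25.6,16.2
15.1,5
2.2,0
3.6,0
0,0
0,2.2
11.6,7.5
22.7,15.8
16.5,14.5
6.1,4.3
0,2.9
6.8,4.3
3.6,2.2
1.5,0
9,5.4
10.4,12.6
18.3,15.4
8.3,6.2
0,3.2
0.4,2.9
0,0.4
0,0.4
8.7,10.8
25.9,12.2
21.7,21.6
8.3,14.8
4.7,13
4.7,17.6
2.2,16.9
10.1,2.1
14,8.2
20.5,21.9
17.6,21.3
5.8,23.5
4.3,26.7
21.6,20.9
12.6,19.1
18.4,20.5
16.6,21.7
23.3,29.9
31,33.1
6.1,23
1.8,22.6
5,29.9
1.8,24.1
0,16.2
14.4,32
14.5,29.4
24.4,14
6.9,25.2
2.5,30.2
4.3,23.4
2.2,31.6
2.5,29.5
15.8,20.1
15.2,30.6
14.4,18.4
7.2,21.2
15.8,14.1
26.3,14.8
32,19.1
32.7,25.3
32.4,24.5
20.2,19.5
13.7,15
21.9,13.3
19.1,9.7
21.2,14
20.1,11.9
20.2,11.1
9,14.3
22,12.3
20.9,17.2
12.6,6.1
0,4.7
0,3.7
4.3,6.1
6.9,4.6
16.6,11.1
15.9,23.4
11.6,21.2
6.9,4.7
0,1.8
0,4.7
0,1.4
2.1,0
4.3,7.2
14.4,17.3
19.5,16.6
5,3.9
0,3.2
4.7,1.8
0,0.7
4,0
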