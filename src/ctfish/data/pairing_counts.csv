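chromosome,stage,n_two_signal,n_one_signal,pct_two_signal,pct_one_signal
1,spermatogonia-early-preleptotene,19,44,30.16,69.84
1,mid-preleptotene-zygotene,14,43,24.56,75.44
1,pachytene,0,52,0.00,100.00
1,round-spermatid,0,113,0.00,100.00
2,spermatogonia-early-preleptotene,13,42,23.64,76.36
2,mid-preleptotene-zygotene,5,34,12.82,87.18
2,pachytene,0,52,0.00,100.00
2,round-spermatid,0,108,0.00,100.00
3,spermatogonia-early-preleptotene,14,48,22.58,77.42
3,mid-preleptotene-zygotene,11,39,22.00,78.00
3,pachytene,0,59,0.00,100.00
3,round-spermatid,0,100,0.00,100.00
4,spermatogonia-early-preleptotene,19,45,29.69,70.31
4,mid-preleptotene-zygotene,12,47,20.34,79.66
4,pachytene,0,55,0.00,100.00
4,round-spermatid,0,121,0.00,100.00
5,spermatogonia-early-preleptotene,20,36,35.71,64.29
5,mid-preleptotene-zygotene,4,37,9.76,90.24
5,pachytene,0,51,0.00,100.00
5,round-spermatid,0,109,0.00,100.00
6,spermatogonia-early-preleptotene,14,35,28.57,71.43
6,mid-preleptotene-zygotene,7,41,14.58,85.42
6,pachytene,0,50,0.00,100.00
6,round-spermatid,0,130,0.00,100.00
7,spermatogonia-early-preleptotene,20,45,30.77,69.23
7,mid-preleptotene-zygotene,11,38,22.45,77.55
7,pachytene,0,60,0.00,100.00
7,round-spermatid,0,100,0.00,100.00
8,spermatogonia-early-preleptotene,12,35,25.53,74.47
8,mid-preleptotene-zygotene,8,36,18.18,81.82
8,pachytene,0,48,0.00,100.00
8,round-spermatid,0,126,0.00,100.00
9,spermatogonia-early-preleptotene,14,31,31.11,68.89
9,mid-preleptotene-zygotene,8,41,16.33,83.67
9,pachytene,0,58,0.00,100.00
9,round-spermatid,0,123,0.00,100.00
10,spermatogonia-early-preleptotene,14,36,28.00,72.00
10,mid-preleptotene-zygotene,11,42,20.75,79.25
10,pachytene,0,62,0.00,100.00
10,round-spermatid,0,123,0.00,100.00
11,spermatogonia-early-preleptotene,5,30,14.29,85.71
11,mid-preleptotene-zygotene,4,47,7.84,92.16
11,pachytene,0,57,0.00,100.00
11,round-spermatid,0,113,0.00,100.00
12,spermatogonia-early-preleptotene,11,30,26.83,73.17
12,mid-preleptotene-zygotene,4,47,7.84,92.16
12,pachytene,0,59,0.00,100.00
12,round-spermatid,0,118,0.00,100.00
13,spermatogonia-early-preleptotene,9,32,21.95,78.05
13,mid-preleptotene-zygotene,12,39,23.53,76.47
13,pachytene,0,43,0.00,100.00
13,round-spermatid,0,104,0.00,100.00
14,spermatogonia-early-preleptotene,16,47,25.40,74.60
14,mid-preleptotene-zygotene,7,52,11.86,88.14
14,pachytene,0,54,0.00,100.00
14,round-spermatid,0,122,0.00,100.00
15,spermatogonia-early-preleptotene,12,30,28.57,71.43
15,mid-preleptotene-zygotene,4,29,12.12,87.88
15,pachytene,0,40,0.00,100.00
15,round-spermatid,0,77,0.00,100.00
16,spermatogonia-early-preleptotene,11,42,20.75,79.25
16,mid-preleptotene-zygotene,10,37,21.28,78.72
16,pachytene,0,59,0.00,100.00
16,round-spermatid,0,85,0.00,100.00
17,spermatogonia-early-preleptotene,9,26,25.71,74.29
17,mid-preleptotene-zygotene,4,32,11.11,88.89
17,pachytene,0,40,0.00,100.00
17,round-spermatid,0,103,0.00,100.00
18,spermatogonia-early-preleptotene,11,18,37.93,62.07
18,mid-preleptotene-zygotene,10,40,20.00,80.00
18,pachytene,0,56,0.00,100.00
18,round-spermatid,0,97,0.00,100.00
19,spermatogonia-early-preleptotene,2,24,7.69,92.31
19,mid-preleptotene-zygotene,1,44,2.22,97.78
19,pachytene,0,49,0.00,100.00
19,round-spermatid,0,76,0.00,100.00
X,spermatogonia-early-preleptotene,10,25,28.57,71.43
X,mid-preleptotene-zygotene,4,44,8.33,91.67
X,pachytene,0,42,0.00,100.00
X,round-spermatid,0,52,0.00,100.00
Y,spermatogonia-early-preleptotene,10,25,,
Y,mid-preleptotene-zygotene,4,44,,
Y,pachytene,0,42,,
Y,round-spermatid,0,52,,
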