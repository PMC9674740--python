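chromosome,stage,signal_kind,n_observations,nvp_pct
1,spermatogonia-early-preleptotene,one_chromosome,38,1.98
1,spermatogonia-early-preleptotene,two_chromosome,44,1.85
1,mid-preleptotene-zygotene,one_chromosome,28,1.94
1,mid-preleptotene-zygotene,two_chromosome,43,2.44
2,spermatogonia-early-preleptotene,one_chromosome,26,1.09
2,spermatogonia-early-preleptotene,two_chromosome,42,2.14
2,mid-preleptotene-zygotene,one_chromosome,10,1.24
2,mid-preleptotene-zygotene,two_chromosome,34,3.59
3,spermatogonia-early-preleptotene,one_chromosome,28,1.21
3,spermatogonia-early-preleptotene,two_chromosome,48,2.07
3,mid-preleptotene-zygotene,one_chromosome,22,1.22
3,mid-preleptotene-zygotene,two_chromosome,39,3.66
4,spermatogonia-early-preleptotene,one_chromosome,38,1.67
4,spermatogonia-early-preleptotene,two_chromosome,45,1.96
4,mid-preleptotene-zygotene,one_chromosome,24,1.22
4,mid-preleptotene-zygotene,two_chromosome,47,3.00
5,spermatogonia-early-preleptotene,one_chromosome,40,0.78
5,spermatogonia-early-preleptotene,two_chromosome,36,2.23
5,mid-preleptotene-zygotene,one_chromosome,8,0.94
5,mid-preleptotene-zygotene,two_chromosome,37,2.47
6,spermatogonia-early-preleptotene,one_chromosome,28,1.11
6,spermatogonia-early-preleptotene,two_chromosome,35,1.84
6,mid-preleptotene-zygotene,one_chromosome,14,1.76
6,mid-preleptotene-zygotene,two_chromosome,41,2.76
7,spermatogonia-early-preleptotene,one_chromosome,40,0.91
7,spermatogonia-early-preleptotene,two_chromosome,45,2.04
7,mid-preleptotene-zygotene,one_chromosome,22,1.76
7,mid-preleptotene-zygotene,two_chromosome,38,2.74
8,spermatogonia-early-preleptotene,one_chromosome,24,0.97
8,spermatogonia-early-preleptotene,two_chromosome,35,1.87
8,mid-preleptotene-zygotene,one_chromosome,16,0.78
8,mid-preleptotene-zygotene,two_chromosome,36,1.97
9,spermatogonia-early-preleptotene,one_chromosome,28,0.53
9,spermatogonia-early-preleptotene,two_chromosome,31,1.21
9,mid-preleptotene-zygotene,one_chromosome,16,0.86
9,mid-preleptotene-zygotene,two_chromosome,41,1.91
10,spermatogonia-early-preleptotene,one_chromosome,28,1.21
10,spermatogonia-early-preleptotene,two_chromosome,36,1.82
10,mid-preleptotene-zygotene,one_chromosome,22,1.70
10,mid-preleptotene-zygotene,two_chromosome,42,2.91
11,spermatogonia-early-preleptotene,one_chromosome,10,1.08
11,spermatogonia-early-preleptotene,two_chromosome,30,1.62
11,mid-preleptotene-zygotene,one_chromosome,8,1.22
11,mid-preleptotene-zygotene,two_chromosome,47,1.87
12,spermatogonia-early-preleptotene,one_chromosome,22,1.23
12,spermatogonia-early-preleptotene,two_chromosome,30,2.63
12,mid-preleptotene-zygotene,one_chromosome,8,1.58
12,mid-preleptotene-zygotene,two_chromosome,47,3.02
13,spermatogonia-early-preleptotene,one_chromosome,18,1.68
13,spermatogonia-early-preleptotene,two_chromosome,32,2.14
13,mid-preleptotene-zygotene,one_chromosome,24,0.65
13,mid-preleptotene-zygotene,two_chromosome,39,2.44
14,spermatogonia-early-preleptotene,one_chromosome,32,1.28
14,spermatogonia-early-preleptotene,two_chromosome,47,1.83
14,mid-preleptotene-zygotene,one_chromosome,14,1.08
14,mid-preleptotene-zygotene,two_chromosome,52,2.29
15,spermatogonia-early-preleptotene,one_chromosome,24,0.64
15,spermatogonia-early-preleptotene,two_chromosome,30,1.18
15,mid-preleptotene-zygotene,one_chromosome,8,0.99
15,mid-preleptotene-zygotene,two_chromosome,29,1.36
16,spermatogonia-early-preleptotene,one_chromosome,22,1.16
16,spermatogonia-early-preleptotene,two_chromosome,42,1.48
16,mid-preleptotene-zygotene,one_chromosome,20,1.59
16,mid-preleptotene-zygotene,two_chromosome,37,2.07
17,spermatogonia-early-preleptotene,one_chromosome,18,0.56
17,spermatogonia-early-preleptotene,two_chromosome,26,1.31
17,mid-preleptotene-zygotene,one_chromosome,8,1.00
17,mid-preleptotene-zygotene,two_chromosome,32,1.53
18,spermatogonia-early-preleptotene,one_chromosome,22,0.78
18,spermatogonia-early-preleptotene,two_chromosome,18,1.21
18,mid-preleptotene-zygotene,one_chromosome,20,1.18
18,mid-preleptotene-zygotene,two_chromosome,40,1.68
19,spermatogonia-early-preleptotene,one_chromosome,4,0.38
19,spermatogonia-early-preleptotene,two_chromosome,24,0.84
19,mid-preleptotene-zygotene,one_chromosome,2,1.46
19,mid-preleptotene-zygotene,two_chromosome,44,1.38
X,spermatogonia-early-preleptotene,one_chromosome,10,1.62
X,spermatogonia-early-preleptotene,two_chromosome,25,1.72
X,mid-preleptotene-zygotene,one_chromosome,4,1.05
X,mid-preleptotene-zygotene,two_chromosome,44,2.84
Y,spermatogonia-early-preleptotene,one_chromosome,10,1.40
Y,spermatogonia-early-preleptotene,two_chromosome,25,2.60
Y,mid-preleptotene-zygotene,one_chromosome,4,2.02
Y,mid-preleptotene-zygotene,two_chromosome,44,1.86
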