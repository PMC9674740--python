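chromosome,size_mb,gc_percent,gene_density,nor
1,195.47,41.3,2687,False
2,182.11,42.2,3491,False
3,160.04,40.7,2225,False
4,156.51,42.5,2622,False
5,151.84,42.7,2507,False
6,149.74,41.6,2597,False
7,145.44,43.2,3798,False
8,129.40,42.6,2177,False
9,124.60,42.9,2276,False
10,130.70,41.6,2086,False
11,122.08,44.0,2852,True
12,120.13,42.0,2002,True
13,120.42,41.9,2127,False
14,124.90,41.4,2111,False
15,104.04,42.2,1620,True
16,98.21,41.2,1367,True
17,94.99,42.9,2005,False
18,90.70,41.7,1218,True
19,61.43,43.1,1283,True
X,171.03,39.2,2291,False
Y,91.74,36.7,423,False
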