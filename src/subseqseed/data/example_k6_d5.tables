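subseqseed-tables v1
k 6
d 5
alphabet ACGT
rc_symmetric 0
rng_seed 0
AF 0 0 52 87 27 79
AF 0 1 46 40 52 70
AF 0 2 56 36 82 91
AF 0 3 99 22 52 23
AF 0 4 99 87 50 29
AF 1 0 79 97 46 19
AF 1 1 57 49 65 87
AF 1 2 70 57 39 72
AF 1 3 56 32 58 70
AF 1 4 62 96 42 38
AF 2 0 98 15 36 34
AF 2 1 14 89 62 39
AF 2 2 65 32 96 25
AF 2 3 21 84 40 97
AF 2 4 17 83 37 70
AF 3 0 23 14 96 60
AF 3 1 98 46 74 31
AF 3 2 72 96 77 79
AF 3 3 41 20 89 99
AF 3 4 38 80 95 82
AF 4 0 70 44 37 87
AF 4 1 78 96 79 32
AF 4 2 98 10 30 98
AF 4 3 92 10 58 97
AF 4 4 61 94 24 35
AF 5 0 84 34 16 30
AF 5 1 48 62 82 43
AF 5 2 69 84 92 51
AF 5 3 94 65 95 52
AF 5 4 87 32 89 44
AR 0 0 15 44 68 42
AR 0 1 28 47 71 79
AR 0 2 48 48 88 14
AR 0 3 64 18 99 60
AR 0 4 11 92 74 96
AR 1 0 15 23 92 33
AR 1 1 96 35 89 87
AR 1 2 12 67 21 83
AR 1 3 43 29 85 99
AR 1 4 39 18 14 70
AR 2 0 37 48 60 99
AR 2 1 84 24 98 19
AR 2 2 51 23 35 79
AR 2 3 66 91 91 26
AR 2 4 29 67 93 31
AR 3 0 46 46 91 94
AR 3 1 14 49 73 31
AR 3 2 49 94 16 44
AR 3 3 48 71 66 62
AR 3 4 35 12 67 35
AR 4 0 93 38 65 86
AR 4 1 96 66 91 80
AR 4 2 91 42 33 72
AR 4 3 11 41 45 45
AR 4 4 60 23 29 24
AR 5 0 79 95 17 44
AR 5 1 26 63 65 23
AR 5 2 77 36 71 48
AR 5 3 29 91 49 63
AR 5 4 99 31 92 71
BF1 0 0 1 -1 -1 1
BF1 0 1 1 -1 -1 1
BF1 0 2 1 -1 -1 1
BF1 0 3 1 1 -1 -1
BF1 0 4 1 -1 1 -1
BF1 1 0 -1 -1 1 1
BF1 1 1 -1 1 -1 1
BF1 1 2 -1 1 1 -1
BF1 1 3 1 1 -1 -1
BF1 1 4 -1 -1 1 1
BF1 2 0 1 1 -1 -1
BF1 2 1 -1 -1 1 1
BF1 2 2 -1 -1 1 1
BF1 2 3 1 -1 -1 1
BF1 2 4 1 -1 1 -1
BF1 3 0 1 -1 1 -1
BF1 3 1 1 -1 -1 1
BF1 3 2 -1 1 1 -1
BF1 3 3 -1 -1 1 1
BF1 3 4 1 1 -1 -1
BF1 4 0 1 -1 1 -1
BF1 4 1 -1 1 1 -1
BF1 4 2 1 1 -1 -1
BF1 4 3 1 -1 -1 1
BF1 4 4 1 -1 1 -1
BF1 5 0 -1 1 -1 1
BF1 5 1 1 -1 1 -1
BF1 5 2 1 -1 -1 1
BF1 5 3 -1 1 1 -1
BF1 5 4 -1 1 1 -1
BF2 0 0 -1 1 -1 1
BF2 0 1 -1 1 -1 1
BF2 0 2 -1 -1 1 1
BF2 0 3 -1 1 1 -1
BF2 0 4 -1 1 1 -1
BF2 1 0 -1 1 1 -1
BF2 1 1 -1 1 1 -1
BF2 1 2 1 1 -1 -1
BF2 1 3 1 -1 1 -1
BF2 1 4 1 -1 1 -1
BF2 2 0 -1 1 -1 1
BF2 2 1 -1 1 -1 1
BF2 2 2 -1 1 1 -1
BF2 2 3 1 -1 1 -1
BF2 2 4 1 1 -1 -1
BF2 3 0 -1 -1 1 1
BF2 3 1 -1 -1 1 1
BF2 3 2 1 -1 1 -1
BF2 3 3 1 -1 1 -1
BF2 3 4 -1 1 -1 1
BF2 4 0 -1 -1 1 1
BF2 4 1 1 -1 1 -1
BF2 4 2 -1 1 1 -1
BF2 4 3 1 1 -1 -1
BF2 4 4 -1 1 1 -1
BF2 5 0 -1 1 1 -1
BF2 5 1 1 1 -1 -1
BF2 5 2 1 1 -1 -1
BF2 5 3 1 -1 1 -1
BF2 5 4 -1 1 -1 1
BR1 0 0 -1 1 -1 1
BR1 0 1 -1 1 1 -1
BR1 0 2 -1 1 1 -1
BR1 0 3 -1 1 1 -1
BR1 0 4 -1 1 -1 1
BR1 1 0 1 -1 -1 1
BR1 1 1 1 -1 1 -1
BR1 1 2 1 -1 -1 1
BR1 1 3 -1 1 -1 1
BR1 1 4 -1 1 1 -1
BR1 2 0 1 1 -1 -1
BR1 2 1 1 -1 1 -1
BR1 2 2 -1 1 -1 1
BR1 2 3 1 1 -1 -1
BR1 2 4 -1 1 1 -1
BR1 3 0 -1 1 -1 1
BR1 3 1 1 -1 1 -1
BR1 3 2 1 -1 -1 1
BR1 3 3 1 1 -1 -1
BR1 3 4 1 -1 -1 1
BR1 4 0 -1 -1 1 1
BR1 4 1 1 -1 1 -1
BR1 4 2 -1 1 1 -1
BR1 4 3 -1 1 1 -1
BR1 4 4 -1 1 1 -1
BR1 5 0 -1 -1 1 1
BR1 5 1 -1 -1 1 1
BR1 5 2 -1 1 -1 1
BR1 5 3 1 -1 1 -1
BR1 5 4 1 -1 1 -1
BR2 0 0 -1 -1 1 1
BR2 0 1 -1 -1 1 1
BR2 0 2 -1 -1 1 1
BR2 0 3 -1 -1 1 1
BR2 0 4 -1 -1 1 1
BR2 1 0 -1 -1 1 1
BR2 1 1 1 -1 -1 1
BR2 1 2 -1 1 -1 1
BR2 1 3 -1 1 1 -1
BR2 1 4 -1 -1 1 1
BR2 2 0 1 -1 -1 1
BR2 2 1 -1 -1 1 1
BR2 2 2 1 1 -1 -1
BR2 2 3 -1 1 -1 1
BR2 2 4 -1 -1 1 1
BR2 3 0 -1 -1 1 1
BR2 3 1 1 1 -1 -1
BR2 3 2 1 1 -1 -1
BR2 3 3 1 -1 -1 1
BR2 3 4 1 1 -1 -1
BR2 4 0 -1 1 1 -1
BR2 4 1 1 1 -1 -1
BR2 4 2 1 -1 1 -1
BR2 4 3 -1 1 -1 1
BR2 4 4 -1 -1 1 1
BR2 5 0 1 -1 1 -1
BR2 5 1 1 -1 1 -1
BR2 5 2 -1 1 1 -1
BR2 5 3 -1 -1 1 1
BR2 5 4 1 1 -1 -1
AP 0 -24 82 -34 11
AP 1 -90 85 33 -95
AP 2 -12 89 29 -12
AP 3 49 71 -73 -18
AP 4 -84 -36 91 70
AP 5 49 -17 -32 16
BP1 0 -1 -1 1 1
BP1 1 -1 -1 1 1
BP1 2 -1 1 -1 1
BP1 3 -1 1 -1 1
BP1 4 1 1 -1 -1
BP1 5 1 -1 1 -1
BP2 0 1 -1 1 -1
BP2 1 1 -1 -1 1
BP2 2 1 -1 -1 1
BP2 3 -1 1 1 -1
BP2 4 1 -1 1 -1
BP2 5 -1 -1 1 1
CF 0 4 2 3 0
CF 1 2 4 3 0
CF 2 1 0 2 4
CF 3 1 3 0 2
CF 4 1 0 4 2
CF 5 1 3 2 4
CR 0 0 3 1 2
CR 1 4 3 1 2
CR 2 4 2 1 0
CR 3 2 1 4 3
CR 4 0 3 4 2
CR 5 3 1 0 2
CP 0 3 1 4 2
CP 1 3 1 4 0
CP 2 3 1 4 0
CP 3 0 2 4 3
CP 4 3 1 4 2
CP 5 4 3 0 2
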