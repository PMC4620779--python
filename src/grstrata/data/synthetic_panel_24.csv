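rsid,chrom,pos,risk_allele,other_allele,allelic_or,risk_allele_freq
rs9000000,1,1000000,A,G,1.1338,0.5639
rs9000001,2,1050000,A,G,1.0751,0.7849
rs9000002,3,1100000,C,A,1.1783,0.54
rs9000003,4,1150000,A,C,1.1515,0.3568
rs9000004,5,1200000,A,C,1.3772,0.7692
rs9000005,6,1250000,A,C,1.3562,0.1179
rs9000006,7,1300000,G,A,1.19,0.1163
rs9000007,8,1350000,G,A,1.2071,0.6927
rs9000008,9,1400000,C,T,1.0726,0.562
rs9000009,10,1450000,G,T,1.3046,0.6145
rs9000010,11,1500000,T,C,1.1369,0.5625
rs9000011,12,1550000,G,A,1.168,0.8911
rs9000012,13,1600000,A,G,1.2118,0.2623
rs9000013,14,1650000,T,G,1.1029,0.3624
rs9000014,15,1700000,T,G,1.135,0.1491
rs9000015,16,1750000,T,G,1.2502,0.2482
rs9000016,17,1800000,G,T,1.0591,0.312
rs9000017,18,1850000,T,C,1.0991,0.4666
rs9000018,19,1900000,G,A,1.1166,0.2885
rs9000019,20,1950000,G,A,1.158,0.1296
rs9000020,21,2000000,T,G,1.3156,0.402
rs9000021,22,2050000,A,G,1.2221,0.2073
rs9000022,1,2100000,G,A,1.2481,0.3334
rs9000023,2,2150000,A,G,1.2772,0.5929
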