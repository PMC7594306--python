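snp	x_j	x_k	p_star
snp1	0	0	0.0030
snp2	0	0	0.0036
snp3	0	0	0.0033
snp4	0	0	0.0021
snp5	1	0	0.1619
snp6	1	0	0.2021
snp7	1	0	0.1410
snp8	1	0	0.1984
snp9	1	0	0.1967
snp10	1	0	0.1735
snp11	1	0	0.1619
snp12	1	0	0.1602
snp13	1	1	0.1585
snp14	1	1	0.1719
snp15	1	1	0.1761
snp16	1	1	0.1796
snp17	1	1	0.2106
snp18	1	1	0.1964
snp19	1	1	0.1844
snp20	1	1	0.2102
snp21	0	1	0.1558
snp22	0	1	0.1519
snp23	0	1	0.1837
snp24	0	1	0.1437
snp25	0	1	0.1431
snp26	0	1	0.1768
snp27	0	1	0.1734
snp28	0	1	0.2051
snp29	0	0	0.0030
snp30	0	0	0.0027
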