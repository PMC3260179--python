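marker_id	rs_id	chromosome	position_bp	allele_codes	note
MID-1470	rs2307666	11	64729920	1,2
MID-777	rs1610863	16	6551830	1,2
MID-196	rs16635	6	99789775	1,2
MID-881	rs1610965	5	79746093	1,2
MID-3122	rs35451359	18	45110983	1,2
MID-548	rs140837	6	3708909	1,2
MID-659	rs1160893	2	224794577	1,2
MID-2011	rs2308203	2	109401291	1,2
MID-2929	rs33974167	8	87813725	1,2
MID-593	rs1160852	6	137345857	1,2
MID-798	rs1610884	5	56122323	1,2
MID-1193	rs2067280	5	89818959	1,2
MID-1871	rs2308067	7	127291541	1,2
MID-17	rs4183	3	3192524	1,2
MID-2538	rs3054057	15	86010538	1,2
MID-1644	rs2307840	1	36099090	1,2
MID-3854	rs60612424	6	84017514	1,2
MID-2275	rs3033053	14	42554496	1,2
MID-94	rs16384	22	42045009	1,2
MID-3072	rs34611875	18	67623917	1,2
MID-772	rs1610859	5	128317275	1,2
MID-2313	rs3045215	1	234740917	1,2
MID-397	rs25621	6	139858158	1,2
MID-1636	rs2307832	1	55590789	1,2
MID-51	rs16343	4	17635560	1,2
MID-2431	rs3031979	8	73501951	1,2
MID-2264	rs34122827	13	63778778	1,2,3	allele 3 = T deletion on long-allele background (2D68Tdel)
MID-2256	rs133052	22	41042364	1,2
MID-128	rs6490	12	108127168	1,2
MID-15	rs4181	2	42577803	1,2
MID-2241	rs3030826	6	67176774	1,2
MID-419	rs140708	6	170720016	1,2
MID-943	rs1611026	5	82545545	1,2
MID-159	rs16438	20	25278470	1,2
MID-2005	rs2308161	10	69800909	1,2
MID-250	rs16687	7	83887882	1,2
MID-1802	rs2307998	5	7814345	1,2
MID-1607	rs2307803	3	108981031	1,2
MID-1734	rs2307930	6	84476378	1,2
MID-406	rs25630	6	14734341	1,2
MID-1386	rs2307582	1	247768775	1,2
MID-1726	rs2307922	1	39896964	1,2
MID-3626	rs11267926	15	45526069	1,2
MID-360	rs25584	12	112145217	1,2,3	allele 3 = T insertion on short-allele background (1D8Tins)
MID-1603	rs2307799	5	70828427	1,2
MID-2719	rs34541393	20	30701405	1,2
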