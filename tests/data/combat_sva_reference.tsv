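s1	s2	s3	s4	s5	s6	s7	s8	s9	s10	s11	s12	s13	s14	s15	s16	s17	s18
g1	 8.55117342120	 8.30021763155	 8.46943501263	 7.99686577157	 8.97588620036	 8.92753223643	 8.52530876704	 9.12500955180	 8.75218840705	 8.00239929707	 7.75654158065	 8.72108659704	 8.47955424051	 8.85271766675	 8.08977276529	 8.48862768670	 8.80663367634	 8.17005280314
g2	 7.29427983270	 6.15880298662	 7.73020740723	 6.93620078910	 6.82079451831	 6.38963587673	 8.01760572218	 6.83984682310	 6.60567699937	 6.67084320612	 7.67930639619	 6.58828082060	 6.87975910396	 6.86153728170	 6.07075167326	 7.71193263004	 6.77921761208	 7.24919241128
g3	 9.09475922101	 8.98090994995	 9.01317413245	 9.02551553815	10.19278380325	 8.37401752301	 8.30181305107	 8.09608419532	 9.07158008389	 9.42158651133	 9.23909817629	 9.21555502805	 9.36614505734	 8.84053743539	 8.67699341077	 8.91340560046	 7.80722957067	 7.97252261281
g4	 7.85021854743	 7.22559490955	 7.23907744543	 8.50781146750	 8.58751096066	 8.45440648287	 7.41481585613	 8.18691662849	 8.08759434881	 8.17532852812	 7.02137181205	 7.33367721500	 8.67426252755	 7.42173782611	 7.94713236318	 9.55676131872	 7.96814630474	 9.01774021142
g5	 6.49008244439	 5.73225796139	 6.26488136354	 5.54975249152	 5.80890666506	 6.17284328981	 3.72981635186	 5.06042682864	 4.88413880539	 4.68702424564	 5.20397271123	 5.83201017203	 5.18982434052	 5.71678732109	 6.73326504059	 4.51874850298	 6.38319963793	 6.21356103601
g6	 8.89301485767	10.13483298863	 8.47861174172	 9.76534783009	 7.90541088204	 8.90835275814	 9.25747526508	 9.55456396321	 9.64226182200	 9.69987430674	 8.96457852718	 8.30759629865	 9.47840609808	 9.01444150196	 9.56133307869	 9.39874782204	10.61717037079	 9.19730719100
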