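table	owner	cscore	dscore	combiscore	selected
singlet	Aloe emodin	9.409090909	0.027118644	5.656302003	1
singlet	Chrysin	8.2	0.044067797	4.937627119	1
singlet	Honokiol	6.133333333	0.054237288	3.701694915	1
singlet	Mevinolin	5.35	0.020338983	3.218135593	1
singlet	Resveratrol	4.559259259	0.013559322	2.740979284	1
singlet	L-ascorbic acid 6-palmitate	2.376470588	0	1.425882353	1
singlet	Cholecalciferol	2.25	0.025423729	1.360169492	1
singlet	Limonene	2.230769231	0.018644068	1.345919166	0
singlet	Cerulenin	2	0.038983051	1.21559322	0
singlet	Retinyl palmitate	1.4	0.005084746	0.842033898	0
singlet	Aloe sin	-1	0.025423729	-0.589830508	0
singlet	Salicin	-10	0.052542373	-5.978983051	0
singlet	Barbaloin	-10	0.037288136	-5.985084746	0
pair	Aloe emodin + honokiol	10.33333333	2.125423729	7.050169492	1
pair	Aloe emodin + Aloe sin	8.833333333	2.588135593	6.335254237	1
pair	Aloe emodin + cholecalciferol	10.25384615	0.376271186	6.302816167	1
pair	Aloe emodin + salicin	8.520754717	2.806779661	6.235164695	1
pair	Aloe emodin + mevinolin	9.523076923	1.154237288	6.175541069	1
pair	Aloe emodin + l-ascorbic acid 6-palmitate	8.968421053	1.637288136	6.035967886	1
pair	Aloe emodin + cerulenin	9.561538462	0.610169492	5.980990874	1
pair	Aloe emodin + barbaloin	8.520754717	1.93220339	5.885334186	1
pair	Aloe emodin + retinylpalmitate	8.945454545	0.86440678	5.713035439	1
pair	Aloe emodin + limonene	9.255932203	0.376271186	5.704067797	1
pair	Aloe emodin + resveratrol	7.910344828	2.313559322	5.671630625	1
pair	Chrysin + l-ascorbic acid 6-palmitate	8.711764706	0.503389831	5.428414756	1
pair	Chrysin + cerulenin	8.784615385	0.284745763	5.384667536	1
pair	Chrysin + salicin	7.838461538	1.672881356	5.372229465	1
pair	Aloe emodin + chrysin	7.87704918	1.418644068	5.293687135	1
pair	Chrysin + barbaloin	7.838461538	0.798305085	5.022398957	1
pair	Mevinolin + chrysin	7.77704918	0.569491525	4.894026118	1
pair	Cholecalciferol + chrysin	6.881481481	1.698305085	4.808210923	1
pair	Honokiol + resveratrol	7.696296296	0.354237288	4.759472693	1
pair	Honokiol + limonene	7.775	0.166101695	4.731440678	1
pair	Mevinolin + resveratrol	6.824489796	1.46440678	4.680456589	1
pair	Honokiol + chrysin	7.609836066	0.166101695	4.632342317	1
pair	Honokiol + cholecalciferol	7.433333333	0.166101695	4.526440678	1
pair	Mevinolin + honokiol	6.385714286	1.276271186	4.341937046	1
pair	Honokiol + cerulenin	7.030769231	0.166101695	4.284902216	1
pair	Mevinolin + limonene	6.885714286	0.305084746	4.25346247	1
pair	Mevinolin + cholecalciferol	6.572727273	0.305084746	4.065670262	0
pair	Honokiol + salicin	6.033333333	0.847457627	3.958983051	0
pair	Mevinolin + salicin	5.15	1.957627119	3.873050847	0
triple	Aloe emodin + mevinolin + honokiol	12.00864198	1.866101695	7.951625863	1
triple	Aloe emodin + honokiol + cholecalciferol	11.74146341	2.125423729	7.89504754	1
triple	Aloe emodin + honokiol + cerulenin	11.49268293	2.047457627	7.714592807	1
triple	Aloe emodin + cholecalciferol + chrysin	11.78888889	1.418644068	7.64079096	1
triple	Aloe emodin + honokiol + limonene	11.15064935	2.125423729	7.540559102	1
triple	Aloe emodin + honokiol + chrysin	11.15064935	1.777966102	7.401576051	1
triple	Aloe emodin + Aloe sin + cholecalciferol	10.45384615	2.588135593	7.30756193	1
triple	Mevinolin + chrysin + barbaloin	9.87704918	0.994915254	6.32419561	1
triple	Aloe emodin + resveratrol + cerulenin	9.046376812	2.23559322	6.322063375	1
triple	Mevinolin + chrysin + l-ascorbic acid 6-palmitate	10.06507937	0.7	6.319047619	1
triple	Mevinolin + chrysin + cerulenin	10.11343284	0.569491525	6.295856312	1
triple	Aloe emodin + mevinolin + l-ascorbic acid 6-palmitate	9.523076923	1.377966102	6.265032595	1
triple	Aloe emodin + mevinolin + retinylpalmitate	9.733333333	0.991525424	6.236610169	1
triple	Mevinolin + honokiol + limonene	9.433333333	1.276271186	6.170508475	1
triple	Honokiol + limonene + resveratrol	10.02258065	0.354237288	6.155243302	1
triple	Mevinolin + honokiol + resveratrol	9.464705882	1.140677966	6.135094716	0
triple	Aloe emodin + Aloe sin + barbaloin	8.833333333	2.069491525	6.12779661	0
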