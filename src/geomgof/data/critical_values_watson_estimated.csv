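theta,alpha,critical_value,statistic,estimated
0.05,0.01,0.3467437413793293,watson,True
0.05,0.025,0.2778376759972572,watson,True
0.05,0.05,0.2274514419363436,watson,True
0.05,0.1,0.17904050038790184,watson,True
0.05,0.15,0.15180609055092734,watson,True
0.05,0.25,0.1187147791302957,watson,True
0.05,0.5,0.07548306455837585,watson,True
0.1,0.01,0.3575281704968666,watson,True
0.1,0.025,0.28627625408424456,watson,True
0.1,0.05,0.23417422960683,watson,True
0.1,0.1,0.1841058999838897,watson,True
0.1,0.15,0.15592791501078324,watson,True
0.1,0.25,0.12166342242736154,watson,True
0.1,0.5,0.0767755780306587,watson,True
0.15,0.01,0.3701706974166472,watson,True
0.15,0.025,0.2959935181295833,watson,True
0.15,0.05,0.24174811568295002,watson,True
0.15,0.1,0.18959893193268507,watson,True
0.15,0.15,0.1602263345403739,watson,True
0.15,0.25,0.12445820091444196,watson,True
0.15,0.5,0.0774088295319428,watson,True
0.2,0.01,0.3847840736236766,watson,True
0.2,0.025,0.306963429971302,watson,True
0.2,0.05,0.2500401735878412,watson,True
0.2,0.1,0.19528082034952202,watson,True
0.2,0.15,0.16440593757430091,watson,True
0.2,0.25,0.12675424628894574,watson,True
0.2,0.5,0.07711468289250947,watson,True
0.25,0.01,0.4011006880793104,watson,True
0.25,0.025,0.31880597741959543,watson,True
0.25,0.05,0.25859483621876644,watson,True
0.25,0.1,0.2006515623880439,watson,True
0.25,0.15,0.16797269408957122,watson,True
0.25,0.25,0.12812822735656118,watson,True
0.25,0.5,0.07575450247257946,watson,True
0.3,0.01,0.4181621916237963,watson,True
0.3,0.025,0.3306356623492405,watson,True
0.3,0.05,0.26660521229507134,watson,True
0.3,0.1,0.20503516146147985,watson,True
0.3,0.15,0.17036599767008104,watson,True
0.3,0.25,0.12821640061600148,watson,True
0.3,0.5,0.0733123459661301,watson,True
0.4,0.01,0.4468020408472553,watson,True
0.4,0.025,0.3485899356197318,watson,True
0.4,0.05,0.2767846314313743,watson,True
0.4,0.1,0.20803443978073383,watson,True
0.4,0.15,0.16964057877994826,watson,True
0.4,0.25,0.12355952265712739,watson,True
0.4,0.5,0.06542121943268056,watson,True
0.45,0.01,0.4531382785119358,watson,True
0.45,0.025,0.35123657856623086,watson,True
0.45,0.05,0.2766798660665616,watson,True
0.45,0.1,0.20537394135102444,watson,True
0.45,0.15,0.16572020288983852,watson,True
0.45,0.25,0.11851591586403405,watson,True
0.45,0.5,0.06016689321809288,watson,True
0.48,0.01,0.45275204944161945,watson,True
0.48,0.025,0.34971933066386685,watson,True
0.48,0.05,0.2742822521173,watson,True
0.48,0.1,0.20212182290211836,watson,True
0.48,0.15,0.1620562111914,watson,True
0.48,0.25,0.1145797309116914,watson,True
0.48,0.5,0.056665159374553783,watson,True
0.49,0.01,0.45179910251894173,watson,True
0.49,0.025,0.34860883128138587,watson,True
0.49,0.05,0.273038124949766,watson,True
0.49,0.1,0.20073690918835274,watson,True
0.49,0.15,0.16060573918315654,watson,True
0.49,0.25,0.1131163589489418,watson,True
0.49,0.5,0.055446161356954266,watson,True
0.5,0.01,0.45040279850954046,watson,True
0.5,0.025,0.34717367907349417,watson,True
0.5,0.05,0.27155667822062873,watson,True
0.5,0.1,0.19919481719949197,watson,True
0.5,0.15,0.1590381947288268,watson,True
0.5,0.25,0.11157809890863549,watson,True
0.5,0.5,0.05420313408156352,watson,True
0.51,0.01,0.448546178513951,watson,True
0.51,0.025,0.3454015831811221,watson,True
0.51,0.05,0.2698294664742844,watson,True
0.51,0.1,0.1974915836764753,watson,True
0.51,0.15,0.15735217723854844,watson,True
0.51,0.25,0.10996564605714362,watson,True
0.51,0.5,0.052937218159154,watson,True
0.52,0.01,0.446213600699428,watson,True
0.52,0.025,0.3432811100574488,watson,True
0.52,0.05,0.26784847901638204,watson,True
0.52,0.1,0.1956233311047786,watson,True
0.52,0.15,0.15554633639670049,watson,True
0.52,0.25,0.10827983808698678,watson,True
0.52,0.5,0.05164958713506129,watson,True
0.55,0.01,0.4362261227357746,watson,True
0.55,0.025,0.3347303193712611,watson,True
0.55,0.05,0.26031136677584077,watson,True
0.55,0.1,0.18899185144429978,watson,True
0.55,0.15,0.14939706969811412,watson,True
0.55,0.25,0.10279247954071692,watson,True
0.55,0.5,0.04766888957248008,watson,True
0.6,0.01,0.4090620050437651,watson,True
0.6,0.025,0.312767002658094,watson,True
0.6,0.05,0.2421238494023623,watson,True
0.6,0.1,0.17433935717833376,watson,True
0.6,0.15,0.13664392344194015,watson,True
0.6,0.25,0.09228705416378216,watson,True
0.6,0.5,0.040728108315885005,watson,True
0.65,0.01,0.3684861939298109,watson,True
0.65,0.025,0.2809578780822881,watson,True
0.65,0.05,0.2167298073665906,watson,True
0.65,0.1,0.15506046112917873,watson,True
0.65,0.15,0.12071809245256397,watson,True
0.65,0.25,0.08022853657791361,watson,True
0.65,0.5,0.033596679506675,watson,True
0.7,0.01,0.3154578017640013,watson,True
0.7,0.025,0.24000827889136575,watson,True
0.7,0.05,0.18463676604301618,watson,True
0.7,0.1,0.13145558193141013,watson,True
0.7,0.15,0.10182001790441206,watson,True
0.7,0.25,0.06681784474862376,watson,True
0.7,0.5,0.02654139280177861,watson,True
0.75,0.01,0.2525557411761157,watson,True
0.75,0.025,0.19183656958215012,watson,True
0.75,0.05,0.1472727800656071,watson,True
0.75,0.1,0.10446607530323773,watson,True
0.75,0.15,0.0806050553523446,watson,True
0.75,0.25,0.052399755464121164,watson,True
0.75,0.5,0.019838111038904063,watson,True
0.8,0.01,0.18415345549307302,watson,True
0.8,0.025,0.1397091767860496,watson,True
0.8,0.05,0.10708913397447727,watson,True
0.8,0.1,0.07575335292835138,watson,True
0.8,0.15,0.05828429409810596,watson,True
0.8,0.25,0.03762830492133243,watson,True
0.8,0.5,0.013714055170120363,watson,True
0.85,0.01,0.11645918130671175,watson,True
0.85,0.025,0.08827506000442592,watson,True
0.85,0.05,0.06758897087735942,watson,True
0.85,0.1,0.04771680145045766,watson,True
0.85,0.15,0.036637941165093606,watson,True
0.85,0.25,0.02353641824702361,watson,True
0.85,0.5,0.008351314941393625,watson,True
0.9,0.01,0.057312058428031554,watson,True
0.9,0.025,0.04341631082727646,watson,True
0.9,0.05,0.033217310484789084,watson,True
0.9,0.1,0.02341951838539361,watson,True
0.9,0.15,0.01795709943254623,watson,True
0.9,0.25,0.011497166637657213,watson,True
0.9,0.5,0.004007664856897208,watson,True
0.95,0.01,0.01558371055298362,watson,True
0.95,0.025,0.011801228537117498,watson,True
0.95,0.05,0.009025014263525389,watson,True
0.95,0.1,0.006358005651393314,watson,True
0.95,0.15,0.004871102248744669,watson,True
0.95,0.25,0.003112655246493097,watson,True
0.95,0.5,0.0010738305308453607,watson,True
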