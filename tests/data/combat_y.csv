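0,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22,23,24,25,26,27,28,29
1.873787112,1.5981752205,1.5472362223,1.5939183013,1.698457498,1.5557829584,1.7872758076,1.5355620532,1.935178304,1.5159570612,2.9758472751,2.3059726134,2.3116470206,2.0698989522,2.3044858837,2.4952683782,2.6066038626,2.457089235,2.3054307055,1.402229103,1.7646459928,1.3328924011,1.3404605021,1.1246880363,1.3591287995,0.8331659756,1.0987857112,1.5443594556,0.8400663569,1.6246310518
2.3670736808,2.8407787733,2.7857127848,2.9700414692,2.5653722994,2.6394964268,2.8416355899,2.418766762,2.5330787869,2.3936411793,3.2348776142,3.4562518775,3.6782333101,4.2564934433,2.8902586534,4.2218934032,3.3696636395,3.5338527911,4.0061109476,3.2993732927,2.3210240172,2.5939424344,2.744463685,2.3331116701,2.3119759767,2.1465065918,2.3847025127,2.3323922734,2.3973654014,2.4256645346
3.4716383139,3.0854298671,3.2417876019,2.7696936987,3.5035087828,2.7842917825,3.4860807251,2.5732138146,3.4504905404,2.9074580085,4.6453867356,3.7103629151,3.7731948282,2.8184715692,4.7621025052,3.7619981827,3.9931466485,3.195228366,4.1564683156,3.4565468554,3.3013992289,2.5529252447,3.4282575729,2.3785033204,2.9751037137,2.7819012068,2.755936844,2.8436170249,2.9856298486,2.2111783905
1.7496096899,2.2744611164,1.5042390088,1.7105428907,1.4509074158,2.3748876686,1.6544321917,2.5298524892,1.7472671788,2.2050463054,2.7729508207,3.3769304732,2.6810926658,2.3251823904,1.5397622938,2.4434974169,1.5949657681,2.791746596,2.2866006602,2.3373847886,1.4304898714,1.7702549216,1.3682215141,1.7053789571,1.3649430174,1.6557201528,0.8738904643,1.9681557568,1.2969520178,1.9609676774
2.8267829963,2.3094700742,2.8565280066,2.3099175641,2.2215669176,2.0709594891,2.2788485196,2.8275032306,3.0569736898,2.6603128043,2.7890876006,3.7687433361,2.9487383067,2.2855984104,3.3025143816,2.9148690163,3.2100080459,3.6691969479,3.2937006632,2.9703210656,2.3865043034,2.5485526247,2.6943369118,1.9973941612,2.3241491171,2.051711736,2.1999897557,2.0969210688,2.1497008997,2.2994446156
2.8776101704,2.3125752532,2.7903018766,2.28028279,3.0721989696,2.3792292837,2.379186785,3.0905741194,3.3822095799,2.6639740305,2.6943947448,3.5012706416,3.5542153283,3.0091570318,2.9691761816,3.2261714685,3.0320392543,3.7624846522,3.0977258142,3.2677509691,2.3995680606,2.4391333342,2.4739403219,1.9113514511,2.1049769031,1.9332814989,1.6932941259,2.1161952567,1.9109959226,2.2110314843
1.5157213139,1.9399205189,0.8937092407,2.1372639658,1.2038583174,1.4832169151,1.2695742799,0.8970295921,1.2663288573,1.7184471268,2.0964008313,2.6161186038,2.4717241116,2.2624193352,1.6654924687,2.9718921097,1.7315857142,2.3627769834,1.425586415,1.9968135938,0.8122407668,1.6855361063,0.7246173223,1.5848124998,0.6734239746,1.2561134736,0.6124817958,1.4514232331,0.7789912805,1.4566852695
3.4544400379,2.9129910164,3.4420955617,2.6341940225,3.0705643221,2.8146733579,2.9218794162,2.9036191513,3.4165183816,2.9614896648,3.6222502047,4.1883080848,3.9526452582,3.2778233551,4.0071506063,3.9421915328,4.1789626894,3.9052307883,3.7424080214,3.1788894638,3.0319584892,2.8893768777,2.8600888478,2.1479062071,2.7224942415,2.6742029228,2.8262151675,2.8418549061,2.628674594,3.2264848792
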