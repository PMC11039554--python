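X0	X1	X2	X3	X4	X5	X6	X7	X8	X9	X10	X11	X12	X13	X14	X15	X16	X17	X18	X19	X20	X21	X22	X23	X24	X25	X26	X27	X28	X29
1.9014880763000797	1.7153838688395109	1.5193301996733874	1.7097194195072591	1.8197021204019377	1.6701732359237127	1.9151780884860512	1.654148877797595	2.047467036651547	1.5653023214141684	2.2831409586923574	1.7972443334807755	1.7809628346767448	1.4772918395333057	1.7432949099038515	1.8533821616890067	2.023241492068329	1.8675107964681033	1.6955534606443785	0.9595571227999454	2.2452961124309283	1.8161969342734343	1.8226521830918003	1.6059472288581356	1.8414464939291408	1.3186791320926827	1.5799247615577183	2.0241456640333464	1.3258396267369437	2.103232681262208
2.5355396223271436	3.079391325706452	3.048780207347663	3.243599760164291	2.7452291077516686	2.8200002249156215	3.103644486649117	2.542337566581228	2.730679056122153	2.5204780258503288	2.617331960048348	2.778403413835662	2.934002617713015	3.4089792073650007	2.378711333968557	3.3658818303319356	2.708282805722819	2.851850559994784	3.203866326259544	2.726583046176009	2.8303206947790556	3.171162341233236	3.37477355345416	2.763600997709782	2.7894520409744423	2.536006960921539	2.844080088841419	2.7959789244473057	2.886683665655304	2.922488301136512
3.576893628994354	3.3589629925269504	3.265783410823079	2.90302640950612	3.669896512916376	2.928019533832275	3.636597851024056	2.69279232588938	3.563920813479394	3.0915587626150454	3.9327556367819434	3.0843988856201654	3.259442460761389	2.358808000528233	3.9647792378489775	3.0980827874117436	3.465879190997952	2.7005217801677284	3.5138428673108906	2.8141336526664773	3.7773665484278096	3.013497229946166	3.9721003372755206	2.8264033610215655	3.3971860859862457	3.3011073894691374	3.1838746768446287	3.3712797133736263	3.416712506905285	2.6449583684565194
1.7541592464509148	2.343595124798238	1.4944603397716512	1.6541539557132916	1.479765809108414	2.474107470999192	1.7129212948086612	2.638681268620329	1.7852860616976851	2.238662600499768	2.087161894099889	2.742453872156084	2.054550833362231	1.8735836060891715	1.2045429366037428	1.9825295358336767	1.2637340076023391	2.2780946784435105	1.6837395974262868	1.8600809275934649	1.9012812524923843	2.095292473206132	1.8641944214604516	2.236586875283303	1.921658156035688	2.0579417816302463	1.2892170067264277	2.505533822294261	1.8908274711308248	2.4419896037105895
2.8544383630009635	2.3465727715832627	2.950566755745583	2.3473328003862006	2.2473398217342138	2.0657479094305566	2.294263957053849	2.936642999666472	3.1867458483542217	2.746770638906245	2.4019625487570617	3.175083632382312	2.5878344334674743	1.9618035438142256	2.7912413646295846	2.4259774764721045	2.7291756055948286	3.0363258295845843	2.7081642774006864	2.4228129636308013	2.749204589062756	2.994246834803997	3.220308921248379	2.475383243204196	2.7967391187535675	2.4412119709071103	2.73519679127344	2.4588748704599084	2.6312555000933298	2.6539825199096128
2.862556719577461	2.3183057648940943	2.7560381575056354	2.2901459104568147	2.962499448713703	2.3703462834841518	2.3724651740012064	3.0260863331930654	3.2750369916428888	2.6387926614819945	2.2870059522301687	2.969360801765084	3.007293939260294	2.502380180855773	2.526435411122499	2.657899248755931	2.5604455769088657	3.1145523768768766	2.56412543241192	2.672882270405581	3.0302818734631582	3.058050225994116	3.145579030253003	2.5446681908483275	2.726700186476138	2.44235166750748	2.1690605330588406	2.6773728641731327	2.519556764705395	2.671561754014419
1.655693120753553	2.0794363918419023	1.0469029020181255	2.271855697625577	1.3464795497989883	1.633675708179732	1.4114442631017912	1.0565695862749243	1.4105983896810508	1.8646096754106607	1.4411126546447743	2.001995298347727	1.6654526706072104	1.6146309527153169	1.047702198641049	2.2256418855641127	1.1763625414894283	1.7919873140708555	0.8447264482986367	1.406471204951015	1.2188082748711944	2.216908861556368	1.2379569752014234	2.1664195756780966	1.0670581680375708	1.6548487965423933	1.1544511416946848	1.9191543753127196	1.2482059818037832	2.028040286152714
3.5270141547546574	3.0238732591923	3.586811933048853	2.666816868719716	3.2053117762370573	2.9123045916787182	2.985280809087297	2.9739534182268312	3.542111821025956	3.048460042652048	3.1658490683054907	3.6216389327778704	3.460416019109311	2.792310886522447	3.453632189737445	3.314069764882695	3.6025826659270765	3.3489293060481264	3.185672257709541	2.6892945979885647	3.462386844698891	3.319814580280159	3.2909287662073785	2.579647525835625	3.152777399717253	3.1027438534049305	3.251116700074798	3.2697016022603926	3.05769420714876	3.651558158084284
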