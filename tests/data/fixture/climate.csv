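population,lon,lat,MAP,MSP,PAS,RH,EMT,EXT,MAT,MCMT,MWMT,TD,DD_0,DD_18,DD5,DD18,NFFD,FFP,bFFP,eFFP,AHM,SHM,CMD,Eref,MAR
P001,-119.31829251425202,48.383167221420791,706.82036366587931,228.38945326643892,111.54790967739132,63.041649765657063,-14.129354047568905,31.747154221320262,7.4141945551979056,-2.3730004605484387,18.327229461632367,20.700229922180807,259.31360536026671,1757.9605802929234,1525.7682917894983,81.596850178448165,183.96911162203801,121.85525075890926,130.78035332750565,252.6356040864149,24.637369620875496,80.245515716751754,28.835219723272399,494.28620662147625,12.944819688972393
P002,-117.57205675040717,47.936858716197833,613.95459960638505,222.47461024676619,136.90153358438093,58.680041835859214,-16.922284226896114,33.419093193425205,5.9282742705990898,-5.4895535057584102,18.552363061479827,24.041916567238239,468.35642385690829,1833.5365387926965,1268.7329306480158,74.128228074128174,157.06968695280577,93.351519064140589,138.9326508873269,232.2841699514675,25.943733104713168,83.390922860373891,77.002103464029389,524.86014043013893,14.450946265755469
P003,-119.61068438944022,44.931707997413575,486.34956498379228,172.57592817532077,46.046643317620237,61.196259220238858,-12.803620485935724,34.595910677852174,9.2133556488013095,-1.1303079757438081,21.251487728855267,22.381795704599075,192.03553633230518,1391.415944698575,1790.0627946303255,99.565834157183076,215.99346258618633,134.73217077512629,119.55178862744582,254.28395940257212,39.505238684528486,123.14282735461096,173.13562231576194,581.80970640849716,15.39072655299216
P004,-114.70566849776458,47.597586669662924,280.24475872193074,101.7753036058901,66.925827686913081,47.624917986851557,-17.798155400965488,37.04589955346286,9.9129225233731457,-4.2523094066919915,24.210823486536128,28.463132893228121,206.09314677102063,1344.6479216379835,1929.2083267946173,123.93305879424346,206.35596165088015,136.62760056080819,119.94312140464089,256.57072196544908,71.055468135022252,237.88505294259775,300.43426398131965,651.85694551032475,15.900078700552505
P005,-119.73679373993946,48.76103684962839,567.75608495422591,186.18501746075916,49.309957252247393,63.730247950905998,-12.864513709001109,36.073528697004633,9.361984525612284,-0.98789054031889023,20.707830442019315,21.695720982338205,155.40004066047226,1304.3214833945053,1987.494445369696,105.38767377501341,212.4102460826071,138.01317205542497,112.09799311364067,250.11116516906566,34.102645552752293,111.22178746946571,40.149222708504865,625.18664683208453,13.885123701236058
P006,-114.68780501577947,49.626320332608174,260.81362102446087,104.81904342622305,93.870633353328472,46.319755265091558,-18.48333770752873,37.210552567606513,7.522098717309933,-6.4410585752372258,24.313828056887523,30.754886632124748,451.55890903948114,1762.8113668163523,1464.3418826435272,146.13549621498473,172.15150017027173,122.45467014188623,133.78826498744559,256.24293512933184,67.182452544020293,231.96002617597659,312.49162518114508,701.82351587878918,16.470871612651692
P007,-115.57613970249038,49.089297561467603,302.36517289866259,106.15381409029189,63.143140214128998,49.911188530894307,-16.998036201741197,36.215815591944981,7.8598441263437397,-5.4922766935085257,23.818420281268608,29.310696974777134,409.98453997138159,1473.3572495408785,1619.5851954868751,128.3635492656712,178.47970781758292,114.03017505648549,124.8328606239467,238.86303568043218,59.06713380753493,224.37649071195153,194.35219291075441,622.30981258076349,15.839043712153657
P008,-117.36243595448184,45.353500071422715,494.30709779234525,180.29320126039937,112.29427366072147,57.587050259659442,-15.547021025189288,34.051907844051101,7.4450725672815325,-3.6296637993307139,20.455630689827675,24.08529448915839,419.38055870708382,1593.3468264145035,1510.6701735356307,92.947562281890129,179.44840603225569,105.81757436618173,130.03873360807913,235.85630797426086,35.291972632385864,113.45758213191517,150.90271359890173,545.78397025397089,14.690135398947607
P009,-114.78196158872606,49.51631435880406,154.6916126918733,38.139001054428505,63.844614631890181,43.132397091027649,-16.851713397135843,39.380094709923739,9.3600505310672091,-5.343393434812735,26.67741597860681,32.020809413419542,422.14754769403402,1252.8818253184147,1892.8168358178891,174.77777072562506,210.27096598323703,140.65462089154423,121.97919111900538,262.6338120105496,125.1525547776792,699.47862400840631,329.41338618441716,743.68240744953891,17.204069966496341
P010,-118.55053473325731,45.452304167217513,669.12215648463769,223.12851561245316,140.19472535233623,59.510352687806943,-18.327541090552014,31.713756473559833,5.1809375140436229,-5.888282434447019,18.401011177739942,24.28929361218696,532.11320632265131,2007.1577591822959,1069.2797223041846,71.825558929157197,143.66164651296523,84.949047808726604,152.77580465445661,237.7248524631832,22.687841624912867,82.468218493866729,65.273055799564005,502.12249988958911,12.813812158218676
P011,-114.58188202087811,47.494273208115338,267.84093952677864,120.0700990452706,60.756780108894546,51.535877291993074,-15.601638096884678,39.132324861685738,9.463418784639904,-3.9605159575861544,24.447599336258943,28.408115293845096,264.57478293520603,1346.3543124491996,1931.0989650563949,159.9813052104239,212.97785754577478,133.76535654663505,120.82570788049213,254.59106442712718,72.667825982942986,203.61105329846816,277.57119696075193,663.86950348475875,16.325682469958618
P012,-114.51847323992118,45.658051190909127,225.14870735283125,86.468531875722505,64.836658613619193,45.098621603308359,-17.881228669830687,39.103714686005148,8.6322057811711055,-6.695875577358156,25.438201254293013,32.134076831651171,445.61960495184843,1544.9081158967556,1779.7575893724395,166.1603410164239,193.76511121684121,126.13018391281716,130.77588417868597,256.90606809150313,82.755108835568464,294.19027595905345,335.7319336713208,684.2560235242936,16.408404754952834
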