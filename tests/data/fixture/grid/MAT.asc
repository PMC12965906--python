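ncols 20
nrows 20
xllcorner -120.0
yllcorner 44.0
cellsize 0.3
NODATA_value -9999.0
10.480194035838126 9.46426086084568 9.906348071834593 9.296072193918231 8.356330742462086 10.80381118996908 8.810709580867842 8.114107697786018 8.26723698084574 9.271516579290513 9.33578572954249 8.581123426580039 8.502905411695204 8.706658591541377 8.797140097104426 7.858000133188542 7.785723884651686 9.02858082607975 8.405461319521295 6.82948825882945
9.664990007905645 9.885492721276846 9.390493948602296 7.960263498050292 8.859451841209127 7.203084209318834 8.89465551592367 7.8697586681555425 7.045233947218248 7.4275366946538055 9.21660887370186 8.603124969738733 7.478963125649457 8.996599139286621 9.109273992365498 8.87360314575152 8.823228020803812 8.231469844152151 8.941763941065654 7.266100389133102
10.599469790507728 7.9620511301756505 8.298358339141958 8.864588148527792 8.301322163993353 8.367143445547327 8.082874470301087 7.835855838531202 8.032887177213903 7.278191587575421 7.721407846205666 8.480054303257411 8.789552863621292 8.008309613496305 9.383649514425734 8.13773481751922 8.734024914179402 8.829782598597841 8.516413549841246 7.196685252336641
9.532519440959472 9.364813120481998 8.384142719694124 7.566541213060678 7.820324863971952 6.319817246241134 5.762334811797013 6.993949411557846 6.786790100363307 7.937985493336712 7.62548171478348 8.500756698571106 7.979809353491552 9.84327858698773 9.47427617923957 8.453893639155423 9.520142168576784 7.645422740354754 8.99703783325059 8.142314303004923
9.683882771358242 9.032623174088016 7.852518864166017 8.02402703926335 6.834152644181015 6.6274060954972125 6.07111388909004 6.31768990214225 7.109117514214864 7.905284852923945 8.217912678107394 8.383498846796796 7.886769612595889 9.67143406122451 9.24252353353788 9.847330471817997 8.928879661445272 9.975801914330786 9.386644336735763 9.557256938280855
8.877739875426345 8.331676957727725 6.390945595142135 7.007904721027754 5.890614032885555 6.192118277392952 5.987505086584433 6.677048516391327 5.248396961733829 7.931587641036028 8.01788899163082 8.796843216003278 8.37162958222144 7.5790789844238144 10.538677545032913 10.10343606044061 10.441487131128492 9.600764219163331 8.215283621312308 8.048839044707153
9.152302545158598 7.463775222600116 7.858016344018489 6.457094162238753 4.49192549971634 5.123381261523721 5.194488436180582 6.252758729774352 7.115551474312766 8.317363027940445 7.44650979569973 8.138082156390105 8.738840834464723 9.598427227555996 9.668638851395936 10.596701327015499 9.636154197684663 9.855153372629564 8.79711950671743 7.822765053101301
8.680386191668902 7.958596643727636 6.990000195208171 7.137087789823526 4.790182990077168 5.728438436913517 4.699923016508614 4.967198470323318 6.07366191983409 5.107032593159899 6.820600539489964 7.620457901633889 8.717168429577349 9.79895473192947 10.848925668393724 9.060223109776635 9.228850544749486 10.269109579204368 8.115518541921086 9.004849506948204
9.206146151457146 9.742400302195836 7.660359335857503 6.077259714777526 4.583361915767265 4.433771823552275 4.660168560303359 6.4230236399832945 4.33084871012525 5.5997007396251535 6.7298767699534086 7.172527952705682 7.879820886514691 9.798999073384534 10.324015861929128 10.901577050465708 9.735164845688427 9.315687536456148 9.257750053056103 8.989725947442857
8.65675670026343 8.263942550275438 6.488044691597771 6.447388143642176 6.480273704291734 5.190703816558958 4.371094446090618 5.32509331589545 4.932456556569595 5.061994255141219 7.051422009847909 7.797040732202124 7.199010895058268 9.905062271744738 10.32829250358021 8.932011138938707 9.999418698197678 9.866654718576827 9.243106984888508 8.469133857868858
8.452895258701831 7.49415373122403 6.944360922045462 4.724265304523678 5.0320225187536565 4.720272233685217 3.8244376177161468 4.513314015534024 4.939373582450459 6.677647398680309 7.370081221060788 7.8982776785708 7.176654549074422 9.142869892837094 10.700232616206357 7.867302197851177 10.305899083959337 9.40337002265503 8.278224085920142 7.66225072311632
9.103842966889236 7.9201550020339155 7.118306445609549 5.356544230051299 4.432360240038922 5.22863979199558 4.459269308151506 4.742081761888989 4.568377012500081 5.844471005129225 5.679345037560702 7.576444680377865 7.411183723864439 9.027017682547696 9.125403473896741 11.292460391101681 9.816576691111388 9.079873390618724 8.659712855337911 7.212427220002722
9.052252636191804 8.792144426489557 7.687193842088922 6.204321988433028 4.7140718316668355 5.614866068812555 3.4421956098633553 3.8151545391883985 5.109440409856722 6.245965924082048 7.503854525046427 7.853478143420077 7.731511520873514 8.218000951149367 8.967517370247668 10.95409925081493 8.886020074217365 9.114014504608114 9.5891611821608 7.467473984404216
8.842335746252473 9.063440413215442 5.919388690746363 5.507234631006055 5.881016021144981 4.606038540339898 6.429905262178604 4.377575179571158 5.08558225753373 5.3271095154560015 7.388618872997944 8.112772463372014 8.053126061779574 8.557933563550495 8.94500670160451 10.531915142650861 9.424886966427431 8.876774026013505 8.421573532730411 6.887373082351731
8.801172056860679 6.784717887407971 6.15003288938559 6.841596306169857 7.30032000717219 5.9207339754272255 5.397332303792676 6.5348592442037425 6.499930699136708 6.698392053404481 6.4895775214381075 7.649357785476313 9.632523951403678 8.39402407796979 9.421690669851627 9.813357719327872 8.19896628598412 7.633008154492237 8.690758974612665 7.641042279266448
9.199182708168594 9.560436749550286 7.405305046499527 6.462189052742538 7.068957493356495 6.066161892091576 4.87303746951694 7.4145182495917945 6.736830022987684 7.026100926759145 6.443466560512863 8.475386660666627 7.741139647056881 8.036258801906433 9.86411217294485 10.512926957897877 8.570586002337024 8.773550008612713 9.033058384746742 6.977983229964632
9.151470022229184 9.211835269985205 8.03791241973329 6.913609650405908 7.117948567548982 6.78611045761107 6.27262670990834 6.736050361476271 6.890167098310328 6.799625687702654 7.2547179547576155 7.005917717084082 8.821148545655467 8.504506074469878 9.264687101648448 8.557677151503253 8.656301812467923 8.41621904724411 8.248972358970176 7.115763033350806
9.41920308113897 8.778285350295107 8.722675092522508 8.246053301334443 8.25078216409118 7.206346573641177 7.9380029204064115 7.730528525044941 7.835806882487662 7.504356577371205 9.528752939567733 8.20395821603863 9.496423758646186 8.142401397117963 9.578315566451368 9.426544367163828 8.463326958953557 8.748499377188018 8.50154991524094 6.458946647852373
10.76044706633716 9.26600851177009 9.210990475392004 8.958902107050971 9.975963356396688 8.953900289262227 8.126558416392273 7.602342459079035 8.55171655579046 7.74345708171508 9.316152852396193 8.857657442614066 10.130426563306827 8.496236464574437 8.499580027128788 8.127555760404789 8.882110783418327 9.711846885228645 8.547632313340323 8.978423625641746
9.86546832181635 11.07812587600044 10.031507509973638 9.98448020027972 10.33071371604166 10.467808841247507 10.549996889691428 9.302343752727808 10.30447140896234 10.026458533590791 9.109477158449376 10.172403792985214 8.498179397692507 8.685630752120852 9.482540181461575 8.748972918052567 8.968307059954562 9.751939003520047 8.556200125223379 8.549849538131712
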