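ncols 20
nrows 20
xllcorner -120.0
yllcorner 44.0
cellsize 0.3
NODATA_value -9999.0
22.529769424873457 22.550636253653874 23.251807815059014 25.161716212843334 26.66122054372363 24.988105946872594 25.668074804512564 27.060753924933532 28.752628321110517 27.071199487559014 28.654959181970128 28.633713484699836 30.043054549951584 29.696128566214057 31.29140315926651 30.194187994871932 30.69612032256654 31.451300978854682 32.00136183401276 33.0078804261138
24.432575728435133 24.619564878557178 23.030872682946338 23.97441443375126 24.724097840621535 26.63675091332098 24.306849799148015 26.3001172695634 25.602599263805853 26.30426047274564 29.088646356862665 29.17977367914288 27.66685876960749 28.51903718963678 30.509664968575095 32.146049487872624 31.31537694563201 31.11818243025609 32.1836565728431 30.074687814727696
23.07783949448471 23.679285842864612 22.2727290003066 22.410403133944673 25.007576873510448 26.858023619742784 26.073940855094847 25.283207851553954 26.814498785365178 28.155447664212584 26.45428079674244 28.829191351343468 28.31373804433501 27.53158004490523 31.321283536113754 30.604481830556544 30.261651023989714 31.71692682340977 32.04146944745308 33.64862561333764
21.374786715374857 22.272315315272014 22.29702629377223 24.3231078948656 22.838532981187644 25.703099772092823 24.3082611800941 26.167573509846306 24.09275641336776 26.25594269382072 26.887784705525338 27.163142973577173 27.524468238459754 29.081864785973995 29.71152565075255 29.169322320314173 31.23967406967764 30.64481886764001 31.47901161853605 30.986975489874
21.75800848694081 22.29767179588382 20.082259891746357 22.865721903987286 21.898169835952302 22.371841689244015 24.043854665708228 24.89085017987816 22.73270115488034 24.624155382008656 26.79574122033961 25.588999411028013 27.15301320648763 27.84646730103599 28.7174569695034 27.010826295534237 31.589280354730917 28.760356355520912 30.428499202114313 30.19454177104953
19.456641161545857 21.96648740245708 19.972382623981517 21.29648278992867 22.03520052888409 22.68131496146076 23.91422370932659 23.759393460471745 23.612652750804223 24.150009418351992 24.370072753520336 25.506180793603036 27.204236116807905 27.438040740431525 27.153371392924726 29.473553554675114 27.76951398787147 28.313041541954043 29.866602132429747 29.84263997181477
18.06339750132906 19.073930040601425 20.631341619607003 21.874551752860288 22.621870048086198 21.573187783791397 22.024361524135504 23.51054366940044 25.40140280302186 24.64870845326345 24.295228986645466 25.864430353574203 25.01940722341361 27.36151381960548 27.175020573573487 29.89497917274799 29.008777952074265 26.648562555596527 29.90643269463002 28.468772750068403
20.347185038907337 20.31479959873471 18.506224660261832 19.468406745814647 20.51735307582565 22.461887456005005 21.328060953531278 21.700192263309958 24.95957192517037 23.605205756641197 26.371537325087267 24.28833700164759 24.50811101910725 27.651393392374302 26.70044090426802 27.731264774046622 28.457380350706064 28.202146283842833 30.400634787874683 30.51816865682313
21.06555388973864 20.294216869590805 20.08843613726061 20.208564349930906 22.126122924959965 20.92744681987684 21.28894776604539 23.19548929888704 22.74418152062793 24.3284694437037 24.39521727873386 25.35370220818615 27.920348871388022 26.426626987095723 28.2073769170418 27.036379369288518 28.754606729112815 28.263559325004877 29.060757184635285 27.98946052816429
20.725131283057635 23.17298414640144 19.777888749966998 21.2957438487983 20.27317553872699 20.482133290367113 21.85007270323576 23.2787694851965 23.896150541741633 23.307444794461066 24.45767488883775 24.96275099256637 25.844961237240526 26.79033791978713 27.567716449134522 28.818332216884826 27.625521072806958 28.20656518564585 29.163650418363346 30.249316547196504
20.818543292487746 19.955667100392752 20.136976071727698 22.28553708700536 21.12909822536608 23.593454985146103 22.455121564892455 22.77708649927336 24.557435268033622 25.852071755659964 24.828278114535415 25.601654814184 26.386868620145002 26.059268526311932 27.23011797795364 29.153549017559612 28.56456386086589 29.090129253844086 30.450650357492464 27.90796858862148
21.281573582754383 22.091368011310415 20.664474576714426 21.301283759067726 23.941429520186155 22.23832937941079 23.887816983999627 23.692826583562393 23.652384147027096 24.15295544435762 25.342215156296657 26.48730853916747 25.541856133635157 26.217354260505285 28.249142359465367 27.7386247867739 30.559646850428038 29.70514066397201 29.985053724714927 31.625695082259455
19.736181697835594 23.146657198952074 23.085634883369703 21.236727702949818 22.771270853091302 25.314598650259047 24.245449188655844 24.08506577417566 25.177580642863614 25.176993580947347 26.396559214679908 27.436820199336076 29.73667940470893 29.342146282966056 27.284391135743213 30.6556668796531 31.70391392837775 31.03048419347265 30.771452060843657 31.693693444537466
21.398921682288226 24.850031575512013 22.743046176352856 24.36033664241961 22.90699194552201 24.313165521725896 23.99736908194531 25.381378024966203 24.605395834800532 27.056974551054886 27.75087657514818 27.43962926857032 25.839394942782214 28.035801413699314 29.601667298706268 31.263416447414595 29.912391548686166 31.17243851102414 29.975326245323746 30.334074962317
22.055582205768953 22.99177738932775 23.680209406298644 22.23079618465913 23.47726683059959 24.006037793965135 25.328364221805465 26.0531905527759 26.045629344479813 27.688182081342138 27.916685213911656 26.90922842554286 28.25596985795226 30.416037327565743 29.88936972149752 29.564903912078144 32.91994008510743 31.63376668207345 31.34004603698503 32.62405565867632
21.969260742029174 24.095107509059602 23.891993031433923 22.813176951160983 25.917552912385247 26.317117092225057 24.678940122951552 26.11070998854716 25.79052506769075 25.652429506525923 27.28686395570824 29.835296213754926 29.151346526060927 29.071046340496387 28.78522136908062 30.16361398068895 30.930281437813374 31.56265702264812 32.271433481615325 32.48706158277815
22.34799596684385 22.372408905878043 22.794424609269996 25.842845805266723 25.45283459691809 24.776358979634566 26.082900608032553 25.051425290012943 26.710972519940402 25.892681480704315 29.005163548895435 29.450600361974224 29.194854697190493 28.851119468090708 30.90889950276074 32.417275810886466 30.703585077678262 30.517481263356323 33.21290321596487 32.08400794829475
22.41016962338191 22.263450507359586 23.32291582572271 23.40217625685877 24.271324225859864 24.399459350932787 26.266197511144284 27.193702924673715 26.434734717163508 26.779565387857442 28.884328625998272 28.02602066436243 28.401555882239208 28.730719438006822 30.883411354549445 29.74073089537366 30.042557796350366 31.520387699083585 31.643564769426074 31.814736830719006
24.570237628329373 21.45307291966999 22.38940814777101 24.735467251876305 23.90098078865414 25.04845481953603 23.929763767434487 25.026837746727338 26.683341722349446 28.57388075761913 27.880056103790693 27.488376207693758 28.13713277348936 28.284087460544367 30.302869668137326 29.962459392737742 30.44811511653888 30.110127331744742 32.081524799970595 31.966136256999384
21.62332980754047 22.12376850104171 21.786941349775873 23.88477814700327 23.573785002727654 24.487230586529957 24.07166195587791 25.55122541361181 25.948165857126718 27.079118362119324 28.163214380110553 26.815677146776437 28.18116909102713 26.855550804039055 29.35672631846205 30.93675991573247 29.29750593123636 31.484072083748277 31.209205329860353 32.8594275518685
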