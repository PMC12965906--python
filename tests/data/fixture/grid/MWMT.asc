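ncols 20
nrows 20
xllcorner -120.0
yllcorner 44.0
cellsize 0.3
NODATA_value -9999.0
21.905395231209198 21.572728337403344 22.313430727573195 22.496148336253654 22.437442229626807 23.18633633742083 22.742012831943573 22.76315560821982 23.310634584631273 23.365663440377897 24.414716742390016 23.76182857801358 24.753221408472914 24.739494192710094 24.994006604505486 24.25582260830007 24.0495136296245 25.931972699671938 25.670804502471466 25.198508755932036
22.159050316241583 22.51259354715442 20.937915927015066 21.06599271095851 22.20887411799842 22.120360273196223 21.88353793150869 21.960075982727485 21.196237720135613 21.692855642542746 24.619661504978655 24.488223170287885 23.0122258966688 24.788526767291618 25.574235956995967 26.37806701979732 25.632814245615037 25.538100987558085 26.54643064681362 24.478172568428636
21.850149559955657 20.775417592940094 20.393181517008827 20.77198166398651 21.403992713165252 22.109506423808718 21.858438149587624 21.252694357368668 22.124092303938912 22.665397263462204 22.127189585211102 23.61884936187772 23.774661581103754 22.902645935967797 26.37701454054174 25.167976629253282 25.322152792375455 25.932740991540086 25.431932844013833 25.600106966114577
21.32861665048107 20.514075796895852 20.42428112588599 20.482494760774347 20.44309853063227 20.635905997385926 18.857407152554845 21.154959389573726 19.960369554260623 22.35641041774174 22.410447175374806 23.212813540868478 22.99983758736893 25.25465171684263 25.23238768757272 23.534361276123292 26.465972938250694 24.45571310634082 25.305175896531395 24.86324986717194
21.129184871686103 20.641663596868856 18.703090229486392 20.20122911293458 18.222731300818605 18.769799747785502 19.43784003796421 19.375120434855887 19.62516909319867 21.072099369470028 22.51331635171432 21.813317812792274 22.17602039600141 24.6881154795041 24.458962164647655 24.12942717244635 26.75913963158804 25.52434542248886 25.61181818167232 25.183158663793506
19.17246447304953 19.379404400235625 17.436881356650265 18.968130885028586 18.312284590393084 18.006267919251158 18.998797626823755 19.08569399433858 18.873532569664 20.974829303177792 20.702969494029773 21.953435924035638 23.161775434832293 22.88424793314058 24.583257206392293 26.31005376607942 24.75199985977325 24.831470503795597 23.850347579761042 24.337813851635136
18.23240408510402 17.9342255496998 18.823945947770582 18.258846494426404 16.780528557184514 16.802703641995347 17.52771776819516 19.104371745411896 20.65920589167163 20.759925034355817 20.714320792303567 21.904913858301782 21.9164513885643 24.767104331569556 23.859188177763258 25.799911027359 25.165506314492617 24.093345163681757 24.93440750680266 24.119785951836704
19.47513086787779 18.387937065810398 16.321010233995256 17.364422173354434 16.70715797163262 17.14689079673885 17.19933380503759 16.262949618098812 19.671639617277417 18.37951898815889 20.89561547281965 19.572320749876106 22.43156675184945 23.793523683106145 25.161548160500786 23.569438238832973 24.871755663626697 25.005516063841064 24.066678513218445 25.088253148492143
20.005153153590683 19.543484752490667 18.066472043229084 17.842886815015998 16.855200555072454 15.787968197459193 16.398787976963366 18.443680060275273 17.693551403254144 18.796313222246596 20.17369086508959 20.776923608153293 23.29065172003315 23.496678478939327 25.40158922572373 24.843646816941625 25.12066262254181 24.736893652037192 24.503194988444637 24.093577943007933
19.75483104792053 20.66434009719685 16.667002615545375 17.39162642378513 17.314347411820624 16.05262236902208 16.232076352322462 18.144134177143304 17.910346189233437 17.747412112236447 20.13969973254096 20.748369334635623 21.63000374786888 24.155575787274277 24.90892250747165 25.191651055381886 24.342039667501663 24.11208702202968 24.79108637175831 24.53989211506662
19.032131753082094 18.077228067151292 17.41101812019579 17.109893781452442 16.036088949777067 17.785676016883627 17.104054134320332 17.388597894561556 18.52541868437105 20.173986290533858 21.01466032095751 21.326270077871996 21.76614186695624 22.566991136249257 24.803827152345274 23.933248136792958 25.57849035084659 25.079014284866485 24.38133537039564 22.2903172127252
19.579930094668658 18.993201560720237 18.808025787202695 17.975273203475354 17.286917603120187 17.534711614342676 17.288907888334485 17.176678721735797 17.685545498353353 18.426466961533393 19.980222328220478 22.804647624574873 21.73982500776408 23.108081976758868 25.04252263440573 25.284021646922337 26.79809271171195 24.562774223362666 25.277193970949444 24.436840628254934
18.757779255130437 21.233669126921914 20.693227858966832 17.690526592058415 17.825568400186356 19.162171652730358 17.016140635633242 17.386457856754966 19.417280068843855 20.089851305775387 22.215903491891176 22.217725739850376 23.713110781154196 24.089811244743085 23.79527844804524 27.6298111004345 26.09670045885482 25.739371536977885 25.682368223170236 24.893328563687565
20.340972034253465 22.252295064488106 18.773175081626682 19.168814759338243 18.284743493771 17.58177081087697 19.053069731110266 18.910033773105862 18.06997949685185 20.12662166012205 21.704939098493607 23.37951003112319 22.099832113283156 24.130093200245483 25.452035351968977 26.97358341594543 25.23486583019809 25.08921731614621 25.536355671855283 23.81799899825454
20.732633969072733 19.28031479539272 18.6969672936368 19.022671022878733 20.091373103531442 19.503606912938466 19.206156033057102 21.31488059789423 21.20682469260043 21.80640377591676 21.718393457819328 21.550347877873293 24.058927582001356 24.985419281106044 25.199401264376018 26.163725421117828 26.67514281417713 24.733389888705105 25.341190881324227 25.64220702564381
21.26004619454704 21.43564436908322 21.31412113421742 18.94580330620708 20.75366356256667 20.775979170891084 19.456321688730714 20.557556075346973 20.930258172842507 21.075381894456743 21.984917388470286 24.874890206960156 24.438576022646224 23.63787030059222 25.47259184960567 25.99772765478032 25.58726668396278 25.434696792294996 25.92348321845761 25.047979563904896
21.880600521952747 20.925955006236613 20.3115924588251 21.339988905883576 21.2885282575135 20.75715993326536 21.55764508662382 20.53808773508297 21.487641618875617 20.418529818253745 23.34318331149829 23.30098930712832 24.269361828378358 24.387201042178813 25.380920297592503 25.61155605962573 25.298627531486396 25.646313597130227 26.505662280887698 24.63743572435948
21.194367510784602 20.39838572267193 21.79538574321499 20.718323696080034 21.33741792566444 20.383943149520547 22.712173339332647 22.5275538343409 22.240942221288883 22.218046761923564 24.58294172252756 23.151222557601628 24.539974685770893 24.0750384985167 26.259007356848684 25.231964691116552 24.913811266963172 25.463157695861813 25.096080351077198 24.040916551170668
23.290763206724584 21.319915391340068 20.87289228997575 22.13141702543227 21.51994658248001 21.493409504295524 21.469456836185675 21.249996260052345 22.523554633428535 23.075054877811265 23.68449664350453 23.933825115811963 24.897617288579305 23.84423749848045 24.30699250009788 24.9835467689423 25.243514979292687 26.071497672430866 26.435724439069443 26.278504887649866
21.127610380517822 22.36049224472093 21.441440206083616 22.274895399255215 23.07803770502572 23.21135081258634 22.852091772084844 22.836242094890764 23.645690495297256 24.39688512631803 24.624835962817382 23.52593693303822 24.377775996988372 22.79684427044092 25.370478696102634 25.47406222633855 24.457713713631115 26.63559257568818 25.745798259052215 26.21869711567366
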