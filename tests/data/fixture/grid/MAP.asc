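ncols 20
nrows 20
xllcorner -120.0
yllcorner 44.0
cellsize 0.3
NODATA_value -9999.0
465.38089388920156 551.4588758878735 406.85931057535805 414.0656756628861 428.37031497206834 384.70898267237277 396.0837812101584 393.66819909526004 296.0789757451395 319.2498160804788 294.54546160753824 331.98030199519974 249.47378626912047 268.9483641965508 186.86748245899892 190.67287905569071 307.0057480384265 170.9773959218432 194.7221279140457 237.23938278310712
507.87942225167865 394.5366978928104 479.5717246377613 493.3432549368449 452.6789750638372 490.20674450607277 451.33303761822816 495.7093086511215 482.97819370945825 533.4221099837644 346.5002359163211 344.8308928113005 415.36027359539844 310.41218847964416 221.62842940736002 248.77930623208482 226.3547540486687 184.53494198854125 96.41910531670455 237.400102028427
449.9787604196939 613.7603898466431 650.3460785825295 515.1007891209005 495.4074712769172 506.64356918538596 458.50377170919154 439.19122026844394 391.85192188526617 428.5072709019638 476.05845115855084 338.8705435163848 370.3272673583101 366.5383673618136 93.64990880824561 254.77216861670166 241.1843769605254 166.43998531728366 183.34788704764392 245.82751402446357
522.4793558913669 602.3906606116943 571.9341041114944 573.6777382743091 572.9305533275522 555.3445976001942 617.4160753871209 474.1095306850301 540.0127967384184 416.6433069875911 430.4214441561642 359.36619670024976 416.252364088619 289.5686714256715 227.33012282055483 312.0718979680065 176.4805395190819 216.26723220134133 232.25617477618596 274.9616805943219
592.9070873023686 557.6764315534006 688.539179648354 603.7237662188521 624.9248829263664 680.6679740344773 667.0128362352648 576.7277142221157 589.1248703726568 462.8675724572356 450.88951632473066 432.5445780323331 367.0511247590838 221.7375120625215 245.00337766220454 301.0631810215435 220.97007281202016 210.3767402722349 192.6950760581213 147.55395502937563
632.8584138757633 699.1180993356844 770.1338817255343 630.2699634007234 715.160967977993 705.6385007349901 642.5266426197882 660.750441792876 688.7285384881525 477.49812147880056 514.8502519839489 430.77777250216496 327.5154236843873 331.3460646256059 287.5716728053295 259.1233867945108 217.67695932036773 283.5423288890939 301.73881848697386 265.9982683188721
650.8846738635767 748.14932828287 714.9100073207242 688.6252110890168 760.9277690898077 754.814893139827 794.1887995919024 708.2198463310563 524.3703447140459 541.3688782106534 539.1108045819157 513.2481950816135 418.5346137643746 323.81570713572467 381.0430155634037 119.53216527245732 205.16702113807835 290.61375994352164 271.24649521756595 280.8594218867215
618.3440910906484 738.3940789897262 868.7158785979898 729.5498810793453 779.3515372094157 805.8146902258653 771.6635961949974 784.3723662542595 659.030567596408 639.4950409147135 535.7191341362927 577.3295888020916 454.7126700571403 315.93332604135713 251.90116418484098 283.49590675815955 237.72922283359185 251.96620779914426 273.87687873249104 221.54942683622724
595.7228554002875 543.3240518425971 753.0812715742861 765.9758807661291 830.4592629918559 835.5599532365102 798.4041731393236 719.0731434985842 712.1933035619255 600.3293503496103 560.1062151147266 568.5739939509959 456.6534302172156 297.363718026575 327.73697373412136 218.5851301692161 249.72097327968504 327.41941627188083 249.55571343355538 269.80197216531377
698.448318551625 529.0779786097314 833.7838594377719 751.6106971456734 734.0363068858196 818.131839151382 813.6013961010048 719.7281143954896 710.2201858315512 753.5649987546274 581.444651119233 488.44170974749983 571.3602300679054 336.53484684364236 266.97010978272033 324.4504412884628 290.2229029943319 233.45085514156295 315.68306918184635 237.47832102268384
721.9872864202866 698.9262600429607 807.7436994430132 801.2043534157109 850.4308242430366 748.7903806661302 802.0697518172921 750.8419923712975 599.852668428003 571.7914086553664 523.411555931668 492.1396865564632 447.55204748702454 394.04304738808673 315.33993748037784 263.69584340719194 287.4941359887567 241.99425731642177 222.01128841895235 372.09014325425215
648.1633735830438 648.490342021654 616.1859553915087 740.263340301012 771.3444352335196 751.0432195262837 703.2449810057251 692.7305604021718 696.730637912647 726.3341066254842 563.2954388971255 444.398344886998 463.0698913586268 309.36066929068147 269.9877665693092 177.8127091225272 162.65438338199777 287.98084179602455 238.75870331859474 265.61231491489093
636.2462125577217 539.1098759843248 562.0719506153778 797.1444244192584 741.9048765139692 742.1653571239622 784.5927986254675 749.0829859230928 583.7728302840344 583.4162543249859 485.20658613009135 341.5613945992649 351.3990404127271 281.2471379781392 351.11479763965593 175.37626470397925 178.0699828299933 128.91729279836667 183.39138687585452 270.6960012139488
566.3976569019997 430.8782362176766 726.8623356002751 661.9683568297086 672.67975530308 719.5656904014754 592.1163728943637 596.9161545894848 700.5954210317736 609.6637914624762 467.0939451370551 390.5960567836025 434.06557151519723 304.30394555624144 275.59639675818926 85.11644257973703 182.2375164452328 194.28057461736117 236.59092853041955 295.99670555608367
576.2167777765881 610.4339208618333 644.3004384733487 640.3419396501574 611.7878039627225 659.7661358135659 575.0516415279876 498.4588670633875 535.2672016758985 470.83309835144604 455.69212517793756 399.47322008711933 302.62021136807107 231.71062016680673 272.46884742353484 191.03391472155687 162.1689516778152 300.38511112956087 209.67584755860014 255.82901935864012
596.6569174638272 505.15484210628574 488.3528179558772 594.8932879335892 519.0583586979449 606.9192867156031 659.360515060192 477.52199535275207 505.78554749776976 488.91141363597836 427.25260775953785 290.27104301117475 259.62850326437575 366.2094249640652 225.82064328499268 220.09004200834102 247.0867476943846 183.6369823107587 93.63028879381378 250.198938822628
465.95935956052267 485.938073218825 492.18157808409427 496.9495635068702 540.9394893646258 517.7554160353329 527.5258948440004 532.1588659444396 475.70100499049454 458.68373698001005 425.82027235451693 387.6519292345766 345.4272122690483 283.2869583166523 236.77093728557696 207.156680947985 167.7406107212966 126.2028778340418 202.605144938099 227.551204159387
470.7443457978236 449.4597004088944 497.6226205555123 559.2678497645053 511.8915361548987 500.0986386281573 481.14151938330434 452.2816708058482 398.6300560530122 404.93428566840805 325.2742109373849 411.1156209839929 232.31382454117184 250.40641385971625 186.0192264726002 172.21447560392448 244.01857337998595 202.5224735185347 224.34490820252194 275.5985781376089
417.36426720799824 491.4616847871917 499.9010166666714 424.7356207695373 454.4085070355156 534.2481462466583 507.27075851172015 485.8021146944765 447.9609150880293 457.0790903147782 365.7570516016741 372.4138810244445 231.5775788716502 332.469092866257 289.3294024394247 287.8260358200858 197.83416851779717 134.24576415013416 178.950539420171 158.68036912018786
518.3006727773551 412.0852755629017 479.7318439325797 488.73813390420065 399.6569255409053 353.85110905641096 425.8428162128291 372.95992863779543 326.62987325630337 316.8334277471088 297.597513653749 339.3425911992735 296.0835533994765 369.6360271205991 269.00568029922124 218.8138243723713 270.4534831794612 131.59377213247285 221.3357068135969 212.8180595454999
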