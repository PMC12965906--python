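ncols 20
nrows 20
xllcorner -120.0
yllcorner 44.0
cellsize 0.3
NODATA_value -9999.0
0.04522943943397989 0.048516981285724285 0.04817354176849375 0.04869162948181301 0.06603930903522737 0.05623284047125359 0.05290605092831001 0.062238850345835796 0.07962825761984044 0.08670583948412179 0.08988386376424175 0.08077933461833049 0.082050793164958 0.0831683482390221 0.0831683482390221 0.07055139061188556 0.0707245716522955 0.089747660955921 0.082050793164958 0.06269117593052981
0.04336908510561669 0.04869162948181301 0.04763137909453125 0.0275642210201012 0.041867240226907534 0.038290085787850356 0.041867240226907534 0.017018246605032136 0.014065665617182596 0.001489295865680057 0.08988386376424175 0.08331530751870916 0.051127485728166694 0.08988386376424175 0.089747660955921 0.0831683482390221 0.0831683482390221 0.07357650060467225 0.089747660955921 0.06269117593052981
0.04522943943397989 0.03454278810133909 0.048523576392510946 0.0495891847267376 0.03805390395701504 0.05278417542264895 0.027272481184169566 0.0220282923666032 0.04630688780238352 0.05145497022159774 0.04555881946736285 0.07962825761984044 0.08072993857504761 0.06766823334282333 0.089747660955921 0.07357650060467225 0.0831683482390221 0.0831683482390221 0.082050793164958 0.06269117593052981
0.048516981285724285 0.052795031986431686 0.048523576392510946 0.008380032884705776 0.03454278810133909 0.008380032884705776 0.008380032884705776 0.014065665617182596 0.030096536253859132 0.02779393517640187 0.049652016867155285 0.07957814707897155 0.058262650159888414 0.089747660955921 0.089747660955921 0.07962825761984044 0.089747660955921 0.06269117593052981 0.089747660955921 0.07357650060467225
0.048516981285724285 0.052795031986431686 0.03454278810133909 0.03454278810133909 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 0.030096536253859132 0.0220282923666032 0.05773509076763825 0.04059945847268069 0.057320553846490874 0.08983785603186924 0.089747660955921 0.08997392230270218 0.089747660955921 0.089747660955921 0.089747660955921 0.089747660955921
0.0495891847267376 0.048523576392510946 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.025641192003879796 0.0189110461498804 0.041867240226907534 0.07957814707897155 0.05948456132514197 0.08983785603186924 0.089747660955921 0.08983785603186924 0.08983785603186924 0.07087291758313971 0.07055139061188556
0.052795031986431686 0.030096536253859132 0.03454278810133909 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 0.03896568435840021 0.008380032884705776 0.023365471976540306 0.041867240226907534 0.08997392230270218 0.08670583948412179 0.089747660955921 0.089747660955921 0.08983785603186924 0.0831683482390221 0.07055139061188556
0.0495891847267376 0.03454278810133909 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 0.030096536253859132 0.027525332126851144 0.008380032884705776 0.0450316970502594 0.08670583948412179 0.08983785603186924 0.0865646364430445 0.089747660955921 0.08983785603186924 0.07357650060467225 0.089747660955921
0.052795031986431686 0.052795031986431686 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 0.008380032884705776 0.008380032884705776 0.058262650159888414 0.08670583948412179 0.08997392230270218 0.08983785603186924 0.089747660955921 0.08997392230270218 0.089747660955921 0.08983785603186924
0.0495891847267376 0.048523576392510946 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 0.018576834211005082 0.0 0.08997392230270218 0.08983785603186924 0.08988386376424175 0.08983785603186924 0.08983785603186924 0.08988386376424175 0.082050793164958
0.048523576392510946 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 0.008380032884705776 0.0 0.016952955946800432 0.038290085787850356 0.056556208827536314 0.08997392230270218 0.06754629082827723 0.089747660955921 0.089747660955921 0.082050793164958 0.05844058931992744
0.052795031986431686 0.03454278810133909 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 0.051127485728166694 0.014065665617182596 0.06530352560496748 0.08983785603186924 0.08983785603186924 0.089747660955921 0.089747660955921 0.0831683482390221 0.06269117593052981
0.052795031986431686 0.04500743619107271 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 -9999.0 0.030096536253859132 0.008380032884705776 0.008380032884705776 0.038290085787850356 0.057320553846490874 0.0677271564646563 0.07357650060467225 0.08670583948412179 0.089747660955921 0.0831683482390221 0.089747660955921 0.089747660955921 0.06269117593052981
0.0495891847267376 0.04578085676989242 0.030096536253859132 0.008380032884705776 0.030096536253859132 0.008380032884705776 0.030096536253859132 0.008380032884705776 0.008380032884705776 0.027525332126851144 0.038290085787850356 0.062238850345835796 0.0220282923666032 0.08326741588333235 0.089747660955921 0.089747660955921 0.089747660955921 0.0831683482390221 0.082050793164958 0.059551582305542666
0.0495891847267376 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.030096536253859132 0.008380032884705776 0.0 0.0 0.038290085787850356 0.038290085787850356 0.038290085787850356 0.08997392230270218 0.082050793164958 0.089747660955921 0.089747660955921 0.07357650060467225 0.06201769198562509 0.0831683482390221 0.06269117593052981
0.048516981285724285 0.048516981285724285 0.012125259960544312 0.030096536253859132 0.008380032884705776 0.008511342627593012 0.008380032884705776 0.007595791859247636 0.008380032884705776 0.014065665617182596 0.038290085787850356 0.082050793164958 0.07055139061188556 0.0677271564646563 0.089747660955921 0.089747660955921 0.0831683482390221 0.0831683482390221 0.089747660955921 0.06269117593052981
0.04522943943397989 0.04763137909453125 0.03454278810133909 0.0 0.0 0.008380032884705776 0.0 0.008380032884705776 0.038290085787850356 0.007595791859247636 0.051205446155005184 0.05203757913367805 0.08331530751870916 0.082050793164958 0.089747660955921 0.0831683482390221 0.0831683482390221 0.082050793164958 0.082050793164958 0.06269117593052981
0.04522943943397989 0.04388310873307779 0.04500743619107271 0.048523576392510946 0.03805390395701504 0.008380032884705776 0.03233930766057125 0.055450862397216985 0.04555881946736285 0.038290085787850356 0.08988386376424175 0.0618913493762418 0.08983785603186924 0.07357650060467225 0.089747660955921 0.089747660955921 0.082050793164958 0.0831683482390221 0.082050793164958 0.06269117593052981
0.05605418153177114 0.048516981285724285 0.052795031986431686 0.04578085676989242 0.04522943943397989 0.04336908510561669 0.031911265186409056 0.014065665617182596 0.06709055140032215 0.05833107510326543 0.08670583948412179 0.08072993857504761 0.08983785603186924 0.07957814707897155 0.082050793164958 0.07357650060467225 0.0831683482390221 0.089747660955921 0.0831683482390221 0.089747660955921
0.048516981285724285 0.04817354176849375 0.04522943943397989 0.04817354176849375 0.0555036301510224 0.06530352560496748 0.0555036301510224 0.06530352560496748 0.06530352560496748 0.08997392230270218 0.08997392230270218 0.08670583948412179 0.08215120850041889 0.08072993857504761 0.089747660955921 0.0831683482390221 0.089747660955921 0.089747660955921 0.0831683482390221 0.0831683482390221
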