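{
 "control:paced": [
  -0.07407330838383293,
  0.10447962670330214,
  0.7733333604414481,
  0.23837839088640628,
  9.30427615857665e-05,
  0.9826539872147713,
  0.9999626811306928,
  0.9986716386248884,
  0.00730720917000953,
  0.4308524298165726,
  0.03286528319297302,
  0.1003572282773131,
  0.8358401450065813,
  0.005817805532262622,
  0.9999999309186393,
  11.502845055936799,
  2.2402246718319467e-05,
  -0.13008827271881382,
  0.013862918885210932,
  0.10488305099798875,
  1.454422322035892e-07,
  2.1162213507065142e-07,
  9.56887106425238e-07,
  2.9997403689988985e-07,
  0.007000473342130538,
  1.899963321047512,
  0.0003932349446600873
 ],
 "control:spontaneous": [
  -0.06219763125936038,
  0.20396121894439934,
  0.22079378600844815,
  0.021619661965635587,
  0.0005128190053402312,
  0.41754990286471955,
  0.9753244964116685,
  0.9941226881574835,
  0.8237838910129033,
  0.3728240564376365,
  0.08810012760189974,
  0.012505971409070985,
  0.547412031956833,
  0.01116152201467431,
  0.9994756883591474,
  11.054358854590381,
  9.743636842149895e-05,
  0.055937034994529615,
  0.06059597296932225,
  0.393387945626861,
  0.0002795934691342989,
  0.0008413023938052916,
  0.004123885492650994,
  0.00013235863158423663,
  0.0072077132275915464,
  1.8388469033582657,
  0.18497400213978143
 ],
 "hcm_r403q:paced": [
  -0.07408536444482547,
  0.10440855923472,
  0.7738708097225552,
  0.2391029299882849,
  9.288170080085382e-05,
  0.9826318444795454,
  0.99996281791214,
  0.9986776363257761,
  0.007254527278863557,
  0.4309124439190963,
  0.03283968183386397,
  0.10058438341412276,
  0.8359885903936319,
  0.005813942216358751,
  0.9999999327939609,
  11.498726089411244,
  2.230029550025139e-05,
  -0.1265049358168487,
  0.013798972268714122,
  0.10438096013248807,
  4.2134868148563817e-07,
  9.274530369508227e-05,
  0.00013676807009715034,
  2.8626316181614236e-05,
  0.007045038125534426,
  1.8978005666532505,
  0.014501763705249911
 ],
 "hcm_r403q:spontaneous": [
  -0.06830397144806936,
  0.14464713075079522,
  0.6089450958385929,
  0.3280369382183701,
  0.00021201138131388996,
  0.9991065776487594,
  0.9998456792702959,
  0.9987448800799514,
  0.0003761881627729561,
  0.40286008062260176,
  0.04626725669579194,
  0.12656278972576845,
  0.7672547043439933,
  0.007889444038885026,
  0.9999999510830418,
  11.081553344546839,
  2.117632300753042e-05,
  0.06509286235556154,
  0.013032816008354953,
  0.09454691681343762,
  9.272490410830198e-08,
  4.317389597597473e-06,
  6.3022182034477065e-06,
  9.878939946818201e-07,
  0.007001553933790175,
  1.8999124810684531,
  0.000501751772169848
 ],
 "mava_0p5uM:paced": [
  -0.07406484394461187,
  0.10452954665189318,
  0.7730874519834995,
  0.23855032999731238,
  9.31555094484474e-05,
  0.9828199501537679,
  0.9999625981331204,
  0.9986658737734254,
  0.007257689834539463,
  0.430810756349677,
  0.03288236766957464,
  0.10057235074678876,
  0.8357474511636477,
  0.005820444331001304,
  0.9999999290753696,
  11.521276179389718,
  2.2500832894388974e-05,
  -0.13749457652975075,
  0.014581389370615852,
  0.10972271558244753,
  1.1856480703526446e-05,
  1.1287482076045204e-06,
  2.2412796241333987e-05,
  1.958268764940493e-06,
  0.007002967231610535,
  1.899552757061974,
  0.0036071310614966367
 ],
 "mava_0p5uM:spontaneous": [
  0.02645565273291817,
  0.9999883099198441,
  0.02409272176068504,
  0.08013772091411211,
  0.9936628381359657,
  0.9495227028709625,
  0.7560630679466094,
  0.9980254921117104,
  0.15215772175197245,
  0.1273124898873545,
  0.08655667256977206,
  0.1098364081352539,
  0.3001661839680379,
  0.4214279334209281,
  0.9999990760471981,
  11.093659801625893,
  3.8312304249264544e-05,
  0.06219537427179465,
  0.01735511352258364,
  0.10785144280547752,
  1.2138065594238889e-05,
  2.3297881590840035e-07,
  3.624919047400959e-06,
  -1.0918714426512062e-08,
  0.006999983498265452,
  1.8999729290700575,
  -2.0784110723692072e-05
 ],
 "bleb_5uM:paced": [
  -0.07408514165409168,
  0.10440988361003489,
  0.7735743942289496,
  0.23815286971495933,
  9.288591373950798e-05,
  0.9827549763002966,
  0.9999627839668535,
  0.9986683687547045,
  0.0073021686788722505,
  0.43091018818445176,
  0.03284236470668355,
  0.10037047137196575,
  0.8359581010877778,
  0.005814199201766951,
  0.999999929878062,
  11.515599167230631,
  2.245797538915436e-05,
  -0.1365078181006443,
  0.013897428255841634,
  0.10514725097207918,
  2.905453866350464e-07,
  0.000425680165950218,
  0.00011488194293012913,
  9.999958905307932e-06,
  0.007035258921936433,
  1.8988411864007608,
  0.003100812275468207
 ],
 "bleb_5uM:spontaneous": [
  -0.06860514407380967,
  0.14221417030388134,
  0.6176306597889833,
  0.32597094551902317,
  0.0002030979755465328,
  0.99904753511771,
  0.9998564793105695,
  0.9987486822492957,
  0.0003963171718921973,
  0.40430389791403837,
  0.0454680815771739,
  0.12653931393932988,
  0.7711761408989254,
  0.007765725804241786,
  0.999999951978677,
  11.090325439009654,
  2.111043645909915e-05,
  0.061357990051585515,
  0.01299506179279209,
  0.09439432361494995,
  9.179752560414445e-08,
  0.0001328404727578914,
  3.58398256027417e-05,
  3.04748594116755e-06,
  0.007010747132405614,
  1.8996435133691025,
  0.0009443104324726276
 ],
 "om_1uM:paced": [
  -0.07360246407408279,
  0.10729288013075129,
  0.7592390071100604,
  0.2313272003001155,
  9.952380787729393e-05,
  0.9833633327781353,
  0.9999578184182355,
  0.9985436094092531,
  0.007751668492521771,
  0.42853812258028356,
  0.033824943965246296,
  0.09829904949174426,
  0.8306596799286556,
  0.005966030315428829,
  0.9999998791932552,
  11.59535682900147,
  2.4587237660626903e-05,
  -0.19004765608928198,
  0.021257277477933302,
  0.36789243457359944,
  4.2085194374169715e-05,
  0.011399648671838649,
  0.01649340048282058,
  0.00018093449259481186,
  0.007919786154895357,
  1.7605928788335719,
  0.10053863441415709
 ],
 "om_1uM:spontaneous": [
  -0.07112617815668475,
  0.12337732432858663,
  0.6897424168632829,
  0.28862069205421537,
  0.00014173816468437085,
  0.9970417099335065,
  0.9999221926630275,
  0.9987158681580195,
  0.001258261163529133,
  0.41646756178396854,
  0.03922050049173462,
  0.11740292417248116,
  0.8025472571684299,
  0.0068007873004708955,
  0.9999999437810166,
  11.15986809193356,
  2.1658790810024407e-05,
  0.045235106361565,
  0.018704779647945077,
  0.3197803374705492,
  2.8226456487086196e-05,
  0.008004375416546788,
  0.011552264444495433,
  0.00018121132387098065,
  0.007924210414608359,
  1.7863344257581373,
  0.09959669107086783
 ]
}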