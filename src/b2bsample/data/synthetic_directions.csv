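name,w_alpha,w_beta,w_gamma,sign_alpha,sign_beta,omega
USS_H,-0.08170897649734951,0.047457802180238394,-0.0005309906874179671,1,1,0.08517200496701964
BETAS_H,-0.10635143257167406,0.08931102766287656,-0.0002142384204709488,1,1,0.03018688305952241
ZS_H,0.2829851167885963,-0.18130609685501778,-7.807776291862761e-05,1,1,-0.14849178568774357
GSS_H,0.24430519357447983,0.1176634402323669,-0.0005408985309217573,1,1,0.11510337828507075
FN11_H,-0.40828356563243506,-0.011700504105156691,-0.0018263914465992382,-1,1,-0.7303465384921253
FN21_H,0.30507819028969557,-0.12670581914671283,-0.0005340407619945337,-1,1,0.3290653572908459
FN31_H,-0.4353207642692016,-0.22377477833048956,0.00019990775882318819,1,-1,-0.30134508747291183
ALPB_H,0.04971564903945261,0.08247726181340286,-0.0006647600584068918,1,1,0.3741114432579074
XFAC_H,-0.38898259518492523,0.02692777793014307,0.0001384324739448953,-1,-1,0.7339442227197002
USS_C,-0.20388630993096454,0.015014256824419786,-0.0016881090410304648,-1,-1,-0.01568994043173188
UPP_C,-0.339092104469243,-0.10399723198945128,-0.000662634296386092,-1,-1,0.2240109151874757
BETAS_C,-0.10741879897429021,-0.02246454404916924,-0.00048059721258140114,1,1,-0.04951581148040405
BETAP_C,-0.042523765775262276,-0.056228910379391074,-0.0002325946444431469,1,-1,0.5435222196409083
ZS_C,-0.5014490037193527,0.15853569635960457,0.0005054783095919714,-1,-1,-0.4498985024357667
ZP_C,0.07835665086952363,-0.02675807143784595,0.0012202545837681669,-1,1,0.2624539711712992
GSS_C,-0.3992670381049474,0.12102065761215715,0.000716514297925036,-1,1,0.1749925080491071
GSP_C,-0.04809383340253631,0.0,-0.0009751963257019291,-1,1,3.141592653589793
GPP_C,0.42173430572151266,-0.01801873712568878,0.0011150321156172573,1,-1,-0.36392971444493966
GP2_C,0.27004046045244257,-0.04588690787843039,0.0007794434918937344,1,-1,-0.026127626306036853
HSP_C,0.7143838786398476,-0.03680095250832907,-0.001044734832813905,-1,-1,-0.44107824926120903
FN11_C,-0.23106019977238304,0.17367907330580723,0.0008385867148874291,-1,1,-0.1688166847504104
FN21_C,0.0,0.09323026897489116,-0.00033349949740933465,1,-1,-0.13516479487433997
FN31_C,0.5883524153077913,0.023421358779806178,0.0006531771034430041,1,-1,-0.2492931209644911
ALPB_HC,-0.7805813770721308,0.0549642987871467,-0.0006635888552541527,1,1,0.052731082093510885
XFAC_HC,0.18295954607831239,0.036334759283499836,0.0017963101068005367,-1,1,0.21655188612374526
ALPC_C,-0.49029761175426845,0.016984276650927933,0.00061972734553035,1,-1,-0.014739917151482238
XFAC_C,0.29777121610738116,0.08933548979702895,0.0009467833234240402,-1,-1,-0.04690166157988193
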