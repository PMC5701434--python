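condition,lambda,family,threshold_sd,uniform_a,uniform_b,n,seed,range_policy,skewness,modal_score,tail_slope,tail_r_squared,error
lam1_sd1,1,normal,1.0,,,10000,379726076,right_tail,2.743222221,1,-0.08267867937,0.8685384247,
lam1_sd2,1,normal,2.0,,,10000,1853975791,right_tail,2.064143348,7,-0.1064691886,0.9596067984,
lam1_sd3,1,normal,3.0,,,10000,1327287812,right_tail,1.621170625,11,-0.139948174,0.9892782885,
lam1_sd4,1,normal,4.0,,,10000,1741119917,right_tail,1.213937229,15,-0.176522433,0.9923380821,
lam2_sd1,2,normal,1.0,,,10000,925733574,right_tail,2.117754791,7,-0.1016557202,0.9517091491,
lam2_sd2,2,normal,2.0,,,10000,515348511,right_tail,1.2614797,16,-0.1776856765,0.9884830841,
lam3_sd1,3,normal,1.0,,,10000,694680028,right_tail,1.617135177,11,-0.1410262694,0.9880230632,
lam3_sd2,3,normal,2.0,,,10000,220160135,right_tail,0.8413768798,20,-0.2373138143,0.9806707587,
lam1_unif0-5,1,uniform,,0.0,5.0,10000,1879133702,full_range,1.602405209,0,-0.08555882604,0.9871247729,
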