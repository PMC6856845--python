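technology,holdout_assay,method,subset,n,TP,FP,TN,FN,mcc,recall,precision,auc,excluded_reason
AlphaScreen,AlphaScreen-P1,bsf,all,26,0,0,14,12,0.0,0.0,0.0,0.776786,
AlphaScreen,AlphaScreen-P1,pains,all,26,0,0,14,12,0.0,0.0,0.0,0.5,
AlphaScreen,AlphaScreen-P1,bsf,SetA,8,0,0,1,7,0.0,0.0,0.0,0.571429,
AlphaScreen,AlphaScreen-P1,pains,SetA,8,0,0,1,7,0.0,0.0,0.0,0.5,
AlphaScreen,AlphaScreen-P1,bsf,SetB,18,0,0,13,5,0.0,0.0,0.0,0.630769,
AlphaScreen,AlphaScreen-P1,pains,SetB,18,0,0,13,5,0.0,0.0,0.0,0.5,
AlphaScreen,AlphaScreen-P2,bsf,all,30,0,0,14,16,0.0,0.0,0.0,0.6875,
AlphaScreen,AlphaScreen-P2,pains,all,30,0,0,14,16,0.0,0.0,0.0,0.5,
AlphaScreen,AlphaScreen-P2,bsf,SetA,5,0,0,0,5,0.0,0.0,0.0,,
AlphaScreen,AlphaScreen-P2,pains,SetA,5,0,0,0,5,0.0,0.0,0.0,,
AlphaScreen,AlphaScreen-P2,bsf,SetB,25,0,0,14,11,0.0,0.0,0.0,0.545455,
AlphaScreen,AlphaScreen-P2,pains,SetB,25,0,0,14,11,0.0,0.0,0.0,0.5,
AlphaScreen,AlphaScreen-P3,bsf,all,26,0,0,17,9,0.0,0.0,0.0,0.545752,
AlphaScreen,AlphaScreen-P3,pains,all,26,0,1,16,9,-0.145521,0.0,0.0,0.470588,
AlphaScreen,AlphaScreen-P3,bsf,SetA,3,0,0,1,2,0.0,0.0,0.0,0.5,
AlphaScreen,AlphaScreen-P3,pains,SetA,3,0,0,1,2,0.0,0.0,0.0,0.5,
AlphaScreen,AlphaScreen-P3,bsf,SetB,23,0,0,16,7,0.0,0.0,0.0,0.46875,
AlphaScreen,AlphaScreen-P3,pains,SetB,23,0,1,15,7,-0.141019,0.0,0.0,0.46875,
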