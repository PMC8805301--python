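# Published confusion counts for ice-ring detection, used as fixture inputs
# to the metric harness (the external tools were not rerun here).
# level=plot rows: per-window histogram classification of one CNN against its
# validation or held-out test plots.  level=dataset rows: whole-dataset
# verdicts on a 197-set labelled benchmark (40 contaminated / 157 clean;
# the amplitude CNN row covers the 154-set subset with amplitude data).
method,level,tp,fp,tn,fn
cnn_fobs_validation,plot,92,8,1556,57
cnn_fobs_test,plot,42,4,973,13
cnn_iobs_validation,plot,37,6,868,11
cnn_iobs_test,plot,69,13,1316,12
phenix_xtriage,dataset,13,13,144,27
ctruncate,dataset,22,64,93,18
auspex_icefinder,dataset,23,16,141,17
p_ice,dataset,29,9,148,11
cnn_iobs,dataset,39,12,145,1
cnn_fobs,dataset,26,4,122,2
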