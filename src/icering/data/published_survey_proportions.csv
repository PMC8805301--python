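# Published numerator/denominator pairs behind headline contamination
# proportions (fixture inputs for the proportion arithmetic).
name,numerator,denominator
contaminated_plot_fraction,984,13170
contaminated_training_sets_fraction,486,1827
benchmark_sets_contaminated_fraction,40,197
pdb_survey_ice_fraction,21741,117615
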