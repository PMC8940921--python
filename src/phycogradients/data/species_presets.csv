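# Phytoplankton per-cell source/sink presets for the phycosphere model.
# radius_um: equivalent spherical radius. exudation_q_*: DOC release,
# fmol C cell^-1 d^-1, per growth phase. uptake_vmax: nitrate uptake vmax,
# fmol N cell^-1 d^-1. uptake_km: uM. bulk_doc_*: ambient labile
# exudate-equivalent background, uM C. bulk_nitrate_*: uM (f/2 nominal in
# exponential phase; depleted in stationary). All rows are literature-scale
# defaults calibrated to the model, not transcribed measurements.
species,radius_um,exudation_q_exp,exudation_q_stat,uptake_vmax,uptake_km,bulk_doc_exp,bulk_doc_stat,bulk_nitrate_exp,bulk_nitrate_stat,provenance
Synechococcus bacillaris,1.0,1.5,3.0,3.0,1.0,0.0004,0.0008,882.0,0.0,literature default
Emiliania huxleyi,2.5,30.0,60.0,20.0,1.5,0.004,0.008,882.0,0.0,literature default
Phaeodactylum tricornutum,3.5,60.0,120.0,25.0,1.8,0.008,0.016,882.0,0.0,literature default
Thalassiosira weissflogii,6.0,150.0,300.0,90.0,2.5,0.006,0.012,882.0,0.0,literature default
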