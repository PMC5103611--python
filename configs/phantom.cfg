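# Bundled phantom experiment: 5 training / 3 held-out synthetic cases at
# the default study conditions. Keys mirror radtrap.pipeline.RunConfig.
seed = 7
n_train = 5
n_test = 3
n_register = 2
lesion_contrast = 0.4
noise_fraction = 0.10
deformation_amplitude = 6.0
mrmr_k = 11
mi_bins = 8
qda_regularization = 0.001
smoothing_sigma_mm = 1.5
threshold = 0.5
focal_margin_mm = 5.0
boost_margin_mm = 2.0
brachy_prescription_gy = 145.0
brachy_boost_gy = 217.5
ebrt_prescription_gy = 79.2
ebrt_boost_gy = 85.8
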